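import itertools

import numpy as np
import pandas as pd
import pytest

from wheatgwas import synthdata
from wheatgwas.synthdata import (
    SimConfig,
    WHEAT_CHROMOSOMES,
    reflectance_from_canopy,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_reflectance,
)


def weir_cockerham_fst(dosages, subpops):
    """Standard multi-population FST estimator on allele frequencies."""
    groups = np.unique(subpops)
    n_i = np.array([(subpops == g).sum() for g in groups], dtype=float)
    p_i = np.array([np.nanmean(dosages[subpops == g], axis=0) / 2 for g in groups])
    nbar = n_i.mean()
    r = len(groups)
    pbar = (n_i[:, None] * p_i).sum(0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return np.nansum(a) / np.nansum(a + b)


class TestConfigValidation:
    def test_fst_bounds(self):
        with pytest.raises(ValueError, match="fst"):
            SimConfig(fst=0.0)
        with pytest.raises(ValueError, match="fst"):
            SimConfig(fst=1.0)

    def test_nonpositive_dimensions(self):
        with pytest.raises(ValueError, match="dimensions"):
            SimConfig(n_accessions=0)

    def test_planted_variance_cannot_exceed_h2(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimConfig(
                planted_qtls=[("1A", 10.0, "yield", 0.5)],
                h2_targets={"yield": 0.4},
            )

    def test_centromere_inside_map(self):
        with pytest.raises(ValueError, match="centromere"):
            SimConfig(centromere_cm=200.0, map_length_cm=150.0)

    def test_wheat_chromosome_names_at_21(self):
        assert SimConfig().chrom_names() == list(WHEAT_CHROMOSOMES)
        assert SimConfig(n_chromosomes=3).chrom_names() == ["chr01", "chr02", "chr03"]


class TestGenotypes:
    def test_seed_determinism_bit_for_bit(self):
        cfg = SimConfig(n_accessions=50, n_chromosomes=2, markers_per_chrom=40, seed=7)
        p1 = simulate_genotypes(cfg)
        p2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(p1.dosages, nan=-1), np.nan_to_num(p2.dosages, nan=-1)
        )
        pd.testing.assert_frame_equal(p1.map, p2.map)

    def test_maf_floor_and_missingness_respected(self, small_panel, small_cfg):
        assert np.nanmin(small_panel.maf()) >= small_cfg.maf_floor - 1e-12
        assert small_panel.missingness().max() <= small_cfg.missing_rate + 1e-12

    def test_map_monotone_and_collinear(self, small_panel):
        for _, sub in small_panel.map.groupby("chrom"):
            assert sub["cm"].is_monotonic_increasing
            assert sub["bp"].is_monotonic_increasing

    def test_no_differentiation_limit(self):
        # as fst -> 0 the between-subpop frequency difference collapses to
        # the finite-sample floor, far below a differentiated panel's
        def mean_abs_dp(fst):
            cfg = SimConfig(
                n_accessions=200, n_subpops=2, fst=fst, n_chromosomes=2,
                markers_per_chrom=100, seed=1, missing_rate=0.0,
            )
            panel = simulate_genotypes(cfg)
            sp = np.array([panel.subpop[a] for a in panel.accession_ids])
            p1 = np.nanmean(panel.dosages[sp == "SP1"], axis=0) / 2
            p2 = np.nanmean(panel.dosages[sp == "SP2"], axis=0) / 2
            return np.mean(np.abs(p1 - p2))

        low, high = mean_abs_dp(0.005), mean_abs_dp(0.3)
        assert low < 0.1
        assert low < 0.4 * high

    def test_fst_recovered_by_weir_cockerham(self):
        cfg = SimConfig(
            n_accessions=1000, n_subpops=2, fst=0.2, n_chromosomes=6,
            markers_per_chrom=150, seed=11, missing_rate=0.0,
        )
        panel = simulate_genotypes(cfg)
        sp = np.array([panel.subpop[a] for a in panel.accession_ids])
        est = weir_cockerham_fst(panel.dosages, sp)
        assert abs(est - 0.2) <= 0.05

    def test_ld_decays_with_distance(self, small_panel):
        chrom = small_panel.map["chrom"].iloc[0]
        mask = (small_panel.map["chrom"] == chrom).to_numpy()
        d = small_panel.dosages[:, mask].copy()
        mu = np.nanmean(d, axis=0)
        ix = np.where(np.isnan(d))
        d[ix] = mu[ix[1]]
        cm = small_panel.map.loc[mask, "cm"].to_numpy()
        corr2 = np.corrcoef(d.T) ** 2
        near, mid, far = [], [], []
        for i, j in itertools.combinations(range(len(cm)), 2):
            dist = abs(cm[i] - cm[j])
            if dist < 2:
                near.append(corr2[i, j])
            elif 5 <= dist < 10:
                mid.append(corr2[i, j])
            elif dist > 30:
                far.append(corr2[i, j])
        assert np.mean(near) > np.mean(mid) > np.mean(far)


class TestPhenotypes:
    def test_layout_honors_check_ratio(self, small_pheno, small_cfg):
        tab, _ = small_pheno
        one = tab[(tab["trait"] == "yield") & (tab["year"] == tab["year"].iloc[0])]
        n_checks = int(one["is_check"].sum())
        n_tests = int((~one["is_check"]).sum())
        assert n_checks == pytest.approx(small_cfg.check_ratio * n_tests, abs=2)
        assert one["row"].notna().all() and one["column"].notna().all()
        assert one["plot_id"].is_unique

    def test_checks_present_every_year(self, small_pheno):
        tab, _ = small_pheno
        checks_by_year = tab[tab["is_check"]].groupby("year")["accession_id"].nunique()
        assert (checks_by_year == 2).all()

    def test_qtl_snaps_to_marker(self, small_panel):
        cfg = SimConfig(
            n_accessions=120, n_chromosomes=2, markers_per_chrom=80, seed=42,
            planted_qtls=[("chr01", 50.0, "yield", 0.1)], h2_targets={"yield": 0.6},
        )
        _, truth = simulate_phenotypes(small_panel, cfg)
        chrom, cm, trait, frac, mid = truth.qtl_positions[0]
        assert mid in small_panel.marker_ids
        assert small_panel.map.loc[mid, "cm"] == cm

    def test_qtl_on_unknown_chromosome_rejected(self, small_panel):
        cfg = SimConfig(
            n_accessions=120, n_chromosomes=2, markers_per_chrom=80, seed=42,
            planted_qtls=[("chr09", 50.0, "yield", 0.1)], h2_targets={"yield": 0.6},
        )
        with pytest.raises(ValueError, match="unknown chromosome"):
            simulate_phenotypes(small_panel, cfg)

    def test_pure_residual_trait_has_no_heritability(self):
        from wheatgwas.quantpheno import fit_mixed_model, heritability

        cfg = SimConfig(
            n_accessions=150, n_chromosomes=2, markers_per_chrom=60, seed=31,
            h2_targets={"flat": 0.0},
        )
        panel = simulate_genotypes(cfg)
        tab, _ = simulate_phenotypes(panel, cfg)
        vc = fit_mixed_model(tab, "flat")
        assert heritability(vc) < 0.1

    def test_determinism(self, small_panel, small_cfg):
        t1, _ = simulate_phenotypes(small_panel, small_cfg)
        t2, _ = simulate_phenotypes(small_panel, small_cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestReflectance:
    def test_bare_soil_at_zero_canopy(self):
        bands = reflectance_from_canopy(np.zeros(3), "anthesis")
        assert (bands == bands[0]).all()
        np.testing.assert_allclose(bands[0], [0.14, 0.18, 0.22, 0.26])

    def test_ndvi_monotone_in_canopy(self):
        bands = reflectance_from_canopy(np.array([0.2, 0.8]), "anthesis")
        ndvi = (bands[:, 3] - bands[:, 1]) / (bands[:, 3] + bands[:, 1])
        assert ndvi[0] < ndvi[1]

    def test_postanthesis_lower_canopy_signal(self, small_panel, small_pheno):
        _, truth = small_pheno
        a = simulate_reflectance(small_panel, truth, "anthesis")
        pa = simulate_reflectance(small_panel, truth, "postanthesis")
        ndvi = lambda t: (t["nir"] - t["red"]) / (t["nir"] + t["red"])
        assert ndvi(pa).mean() < ndvi(a).mean()

    def test_unknown_stage_rejected(self, small_panel, small_pheno):
        _, truth = small_pheno
        with pytest.raises(ValueError, match="stage"):
            simulate_reflectance(small_panel, truth, "booting")

    def test_reflectance_heritable_canopy_correlates_with_genetics(
        self, small_panel, small_pheno
    ):
        _, truth = small_pheno
        spec = simulate_reflectance(small_panel, truth, "anthesis", h2_canopy=0.8)
        g = truth.genetic_values["yield"].to_numpy()
        ndvi = ((spec["nir"] - spec["red"]) / (spec["nir"] + spec["red"])).to_numpy()
        assert np.corrcoef(g, ndvi)[0, 1] > 0.5
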