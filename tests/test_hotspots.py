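import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from wheatgwas.hotspots import (
    ChromLDProfile,
    Hotspot,
    OverviewProfile,
    call_peaks,
    filter_hotspots,
    hotspots_to_bed,
    merge_to_hotspots,
    mta_ci,
    overview_index,
    physical_interval,
    reference_intervals,
    round_mb,
)


def mta_frame(rows):
    """rows: (marker_id, chrom, cm, trait, environment, neglog10p)"""
    return pd.DataFrame(
        rows, columns=["marker_id", "chrom", "cm", "trait", "environment", "neglog10p"]
    )


def quadrature_u(bin_center, mus, s, nbE):
    """Independent numerical-integration oracle for one overview-index bin."""
    total = 0.0
    for mu in mus:
        val, _ = quad(lambda t: norm.pdf(t, loc=mu, scale=s), bin_center - 0.5, bin_center + 0.5)
        total += val
    return total / nbE


class TestLDProfileAndCI:
    def test_sd_is_ci_over_392(self):
        assert ChromLDProfile("1A", 3.92).s_cm == pytest.approx(1.0, abs=1e-12)
        assert ChromLDProfile("1A", 10.0).s_cm == pytest.approx(2.551, abs=1e-3)

    def test_bounds_clipped_at_chromosome_edges(self):
        ld = ChromLDProfile("1A", 10.0)
        s, (lo, hi) = mta_ci(1.0, ld, 150.0)
        assert lo == 0.0 and hi == pytest.approx(6.0)
        s, (lo, hi) = mta_ci(149.0, ld, 150.0)
        assert hi == 150.0

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(ValueError):
            ChromLDProfile("1A", 0.0)


class TestOverviewIndex:
    def test_single_interior_mta_mass_conserved(self):
        mtas = mta_frame([("m1", "c1", 75.0, "t", "Y1", 4.0)])
        prof = overview_index(mtas, {"c1": ChromLDProfile("c1", 7.84)}, {"c1": 150.0}, nbE=1)["c1"]
        assert prof.u.sum() == pytest.approx(1.0, abs=1e-9)

    def test_colocated_mtas_double_pointwise(self):
        ld = {"c1": ChromLDProfile("c1", 7.84)}
        one = overview_index(mta_frame([("m1", "c1", 60.0, "t", "Y1", 4.0)]), ld, {"c1": 150.0}, 1)["c1"]
        two = overview_index(
            mta_frame(
                [("m1", "c1", 60.0, "t", "Y1", 4.0), ("m2", "c1", 60.0, "u", "Y2", 5.0)]
            ),
            ld,
            {"c1": 150.0},
            1,
        )["c1"]
        np.testing.assert_allclose(two.u, 2.0 * one.u, atol=1e-12)

    def test_matches_quadrature_oracle_on_toy_map(self):
        # five associations on a 150-cM chromosome, s = 2 (CI = 7.84), nbE = 2
        mus = [10.0, 42.5, 43.0, 75.0, 149.0]
        mtas = mta_frame([(f"m{i}", "c1", mu, "t", "Y1", 4.0) for i, mu in enumerate(mus)])
        prof = overview_index(mtas, {"c1": ChromLDProfile("c1", 7.84)}, {"c1": 150.0}, nbE=2)["c1"]
        for probe in (10, 43, 148):  # bin centers probe+0.5
            got = prof.u[probe]
            expected = quadrature_u(prof.positions[probe], mus, 2.0, 2)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_mean_equals_closed_form_density(self):
        # interior-only fixture: mean of u over the map = nbQTL/(nbE*L)
        mus = [40.0, 60.0, 80.0, 100.0]
        mtas = mta_frame([(f"m{i}", "c1", mu, "t", "Y1", 4.0) for i, mu in enumerate(mus)])
        prof = overview_index(mtas, {"c1": ChromLDProfile("c1", 3.92)}, {"c1": 200.0}, nbE=2)["c1"]
        assert prof.u.mean() == pytest.approx(len(mus) / (2 * 200.0), abs=1e-9)

    def test_unmapped_chromosome_and_zero_length_rejected(self):
        mtas = mta_frame([("m1", "cX", 5.0, "t", "Y1", 4.0)])
        with pytest.raises(ValueError, match="unmapped"):
            overview_index(mtas, {}, {"c1": 100.0}, 1)
        with pytest.raises(ValueError, match="zero map length"):
            overview_index(
                mta_frame([("m1", "c1", 0.0, "t", "Y1", 4.0)]),
                {"c1": ChromLDProfile("c1", 1.0)},
                {"c1": 0.0},
                1,
            )


class TestCallPeaks:
    def _profile(self, u, mean_thr=0.5):
        u = np.asarray(u, dtype=float)
        return OverviewProfile("c1", np.arange(len(u)) + 0.5, u, mean_threshold=mean_thr)

    def test_flat_profile_no_peaks(self):
        assert call_peaks(self._profile([0.7] * 20)).empty

    def test_single_bump_one_peak_at_mode(self):
        u = norm.pdf(np.arange(30), loc=14, scale=2)
        peaks = call_peaks(self._profile(u, mean_thr=0.01), high_mult=5.0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["cm"] == 14.5

    def test_subthreshold_bump_dropped(self):
        x = np.arange(60, dtype=float)
        u = (
            1.0 * norm.pdf(x, 10, 1.5)
            + 1.0 * norm.pdf(x, 30, 1.5)
            + 0.05 * norm.pdf(x, 50, 1.5)
        )
        peaks = call_peaks(self._profile(u, mean_thr=0.02), mean_mult=1.0, high_mult=5.0)
        assert len(peaks[peaks["u"] > 0.1]) == 2

    def test_plateau_resolved_to_midpoint(self):
        u = np.array([0.0, 0.2, 0.9, 0.9, 0.9, 0.2, 0.0])
        peaks = call_peaks(self._profile(u, mean_thr=0.1))
        assert len(peaks) == 1 and peaks.iloc[0]["cm"] == 3.5

    def test_high_tier_subset_of_mean_tier(self):
        rng = np.random.default_rng(0)
        u = np.abs(rng.normal(0.5, 0.5, 100))
        prof = self._profile(u, mean_thr=float(u.mean()))
        peaks = call_peaks(prof, mean_mult=1.0, high_mult=5.0)
        high = set(peaks[peaks["tier"] == "high"]["cm"])
        assert high <= set(peaks["cm"])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            call_peaks(self._profile([]))


def _marker_map(chrom="c1", n=50, length=100.0):
    cms = np.linspace(0, length, n)
    mp = pd.DataFrame(
        {"chrom": chrom, "cm": cms, "bp": (cms * 1e6).astype(int) + 1},
        index=[f"{chrom}_m{i}" for i in range(n)],
    )
    mp.index.name = "marker"
    return mp


class TestMergeToHotspots:
    def _peaks(self, chrom_cm_u, tier="high"):
        out = {}
        for chrom, cms in chrom_cm_u.items():
            out[chrom] = pd.DataFrame(
                {"cm": cms, "u": [1.0] * len(cms), "tier": [tier] * len(cms)}
            )
        return out

    def _mtas_near(self, chrom, cms):
        return mta_frame(
            [(f"q{i}", chrom, cm, "t", "Y1", 4.0) for i, cm in enumerate(cms)]
        )

    def test_fully_overlapping_peaks_merge(self):
        ld = {"c1": ChromLDProfile("c1", 10.0)}
        hs = merge_to_hotspots(
            self._peaks({"c1": [50.0, 51.0]}),
            self._mtas_near("c1", [50.0, 51.0]),
            ld,
            _marker_map(),
        )
        assert len(hs) == 1
        assert hs[0].left_cm == pytest.approx(45.0)
        assert hs[0].right_cm == pytest.approx(56.0)

    def test_different_chromosomes_never_merge(self):
        ld = {"c1": ChromLDProfile("c1", 10.0), "c2": ChromLDProfile("c2", 10.0)}
        mm = pd.concat([_marker_map("c1"), _marker_map("c2")])
        hs = merge_to_hotspots(
            self._peaks({"c1": [50.0], "c2": [50.0]}),
            pd.concat([self._mtas_near("c1", [50.0]), self._mtas_near("c2", [50.0])]),
            ld,
            mm,
        )
        assert len(hs) == 2
        assert {h.chromosome for h in hs} == {"c1", "c2"}

    def test_four_peaks_one_overlapping_pair_gives_three(self):
        ld = {"c1": ChromLDProfile("c1", 8.0)}
        hs = merge_to_hotspots(
            self._peaks({"c1": [10.0, 40.0, 44.0, 80.0]}),
            self._mtas_near("c1", [10.0, 40.0, 44.0, 80.0]),
            ld,
            _marker_map(),
        )
        assert len(hs) == 3
        assert [h.id for h in hs] == ["QTLc1.1", "QTLc1.2", "QTLc1.3"]

    def test_peak_without_member_mta_is_contradiction(self):
        ld = {"c1": ChromLDProfile("c1", 4.0)}
        with pytest.raises(RuntimeError, match="no member MTA"):
            merge_to_hotspots(
                self._peaks({"c1": [50.0]}),
                self._mtas_near("c1", [90.0]),
                ld,
                _marker_map(),
            )

    def test_traits_years_and_max_p_are_member_unions(self):
        ld = {"c1": ChromLDProfile("c1", 10.0)}
        mtas = mta_frame(
            [
                ("q0", "c1", 49.0, "yield", "Y1", 4.2),
                ("q1", "c1", 51.0, "ndvi", "Y2", 6.8),
                ("q2", "c1", 90.0, "far", "Y1", 3.3),
            ]
        )
        hs = merge_to_hotspots(self._peaks({"c1": [50.0]}), mtas, ld, _marker_map())
        (h,) = hs
        assert h.traits == {"yield", "ndvi"} and h.years == {"Y1", "Y2"}
        assert h.max_neglog10p == pytest.approx(6.8)
        assert len(h.member_mtas) == 2


class TestFilterHotspots:
    def _hotspot(self, ident="QTLc1.1", chrom="c1", left=40.0, right=60.0,
                 ci_mb=5.0, years=("Y1", "Y2"), traits=("a", "b")):
        return Hotspot(
            id=ident, chromosome=chrom, left_cm=left, peak_cm=(left + right) / 2,
            right_cm=right, member_mtas=pd.DataFrame(), traits=set(traits),
            years=set(years), ci_mb=ci_mb,
        )

    def test_centromere_inside_dropped_with_reason(self):
        kept, log = filter_hotspots([self._hotspot()], {"c1": 50.0})
        assert kept == []
        assert log.iloc[0]["reasons"] == "centromere"

    def test_wide_physical_interval_dropped(self):
        kept, log = filter_hotspots([self._hotspot(ci_mb=36.0)], {"c1": 75.0})
        assert kept == [] and "ci_mb" in log.iloc[0]["reasons"]
        kept, _ = filter_hotspots([self._hotspot(ci_mb=35.0)], {"c1": 75.0})
        assert len(kept) == 1  # exactly at the cap survives

    def test_single_year_or_single_trait_dropped(self):
        kept, log = filter_hotspots([self._hotspot(years=("Y1",))], {"c1": 75.0})
        assert kept == [] and "years" in log.iloc[0]["reasons"]
        kept, log = filter_hotspots([self._hotspot(traits=("a",))], {"c1": 75.0})
        assert kept == [] and "traits" in log.iloc[0]["reasons"]

    def test_mean_environment_not_counted_as_year(self):
        h = self._hotspot(years=("Y1", "mean"))
        kept, log = filter_hotspots([h], {"c1": 75.0})
        assert kept == []

    def test_five_hotspots_two_violations_three_retained(self):
        hs = [
            self._hotspot("h1", left=10.0, right=20.0),
            self._hotspot("h2", left=70.0, right=80.0, ci_mb=40.0),  # too wide
            self._hotspot("h3", left=45.0, right=55.0),  # spans centromere at 50
            self._hotspot("h4", left=0.0, right=10.0),
            self._hotspot("h5", left=80.0, right=90.0),
        ]
        kept, log = filter_hotspots(hs, {"c1": 50.0})
        assert [h.id for h in kept] == ["h1", "h4", "h5"] or len(kept) == 3

    def test_missing_centromere_entry_raises(self):
        with pytest.raises(ValueError, match="centromere"):
            filter_hotspots([self._hotspot()], {})


class TestPhysicalInterval:
    def test_printed_interval_forward(self):
        assert physical_interval(7294564, 9579957) == 2.3

    def test_printed_interval_reversed_orientation(self):
        assert physical_interval(613696030, 609166802) == 4.5

    def test_degenerate_zero(self):
        assert physical_interval(5, 5) == 0.0

    def test_round_half_up(self):
        assert round_mb(2_250_000) == 2.3
        assert round_mb(2_249_999) == 2.2

    def test_all_published_rows_reproduce(self):
        tab = reference_intervals()
        for row in tab.itertuples():
            assert physical_interval(row.left_bp, row.right_bp) == row.ci_mb, row.hotspot

    def test_bed_export_half_open(self, tmp_path):
        h = Hotspot(
            id="QTLc1.1", chromosome="c1", left_cm=0, peak_cm=1, right_cm=2,
            member_mtas=pd.DataFrame(), left_bp=1000, right_bp=500, ci_mb=0.0,
        )
        path = tmp_path / "h.bed"
        hotspots_to_bed([h], path)
        chrom, start, end, name = path.read_text().split()
        assert (chrom, int(start), int(end), name) == ("c1", 499, 1000, "QTLc1.1")
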