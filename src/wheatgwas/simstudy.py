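"""Validation experiments on synthetic panels, with fixed study designs.

Each function runs one self-contained simulation experiment and returns the
quantities a validation study cares about.  The designs are frozen here so
the test suite and the reproduction script exercise identical conditions:

* calibration: n = 300 accessions in 6 subpopulations at FST 0.2, 500
  markers; phenotype = subpopulation effect + unit noise (no marker effect),
  so any per-marker signal is stratification leakage.
* power: one planted QTL explaining 10% of phenotypic variance, scanned on
  the across-year accession means.
* heritability recovery: 200 accessions x 3 years, two-stage REML against
  generating values.
* hotspot recovery: a planted cluster (one position affecting 2 traits,
  scanned in 2 years) on a 10-chromosome, 1500-marker genome at the panel
  scale of the emulated study (300 accessions), run through the full
  MTA -> overview-index -> peak -> merge -> exclusion pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hotspots, mlmgwas, quantpheno, synthdata

__all__ = [
    "null_calibration",
    "qtl_power",
    "h2_recovery",
    "hotspot_recovery",
]


def _acc_means(tab: pd.DataFrame, trait: str, year: str | None = None) -> pd.DataFrame:
    sub = tab[tab["trait"] == trait]
    if year is not None:
        sub = sub[sub["year"] == year]
    return sub.groupby("accession_id")["value"].mean().rename(trait).to_frame()


def null_calibration(seed: int) -> dict:
    """MLM vs naive genomic inflation on a structured null phenotype.

    The phenotype carries subpopulation means plus unit noise and no marker
    effect; a calibrated scan has lambda near 1, while naive OLS inflates.
    Also reports the fraction of markers with p < 0.05 for the mixed model.
    """
    cfg = synthdata.SimConfig(
        n_accessions=300,
        n_subpops=6,
        fst=0.2,
        n_chromosomes=5,
        markers_per_chrom=100,
        seed=seed,
    )
    panel = synthdata.simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 10_000)
    sp_eff = rng.normal(0.0, 1.0, cfg.n_subpops)
    sp_ix = np.array([int(panel.subpop[a][2:]) - 1 for a in panel.accession_ids])
    y = sp_eff[sp_ix] + rng.normal(0.0, 1.0, cfg.n_accessions)
    phenos = pd.DataFrame({"trait": y}, index=panel.accession_ids)
    gcfg = mlmgwas.GwasConfig(cofactors=[])
    scan = mlmgwas.mlm_scan(panel, phenos, "trait", gcfg)
    naive = mlmgwas.naive_scan(panel, phenos, "trait")
    p_mlm = 10 ** (-scan["neglog10p"].dropna())
    p_naive = 10 ** (-naive["neglog10p"].dropna())
    return {
        "lambda_mlm": mlmgwas.genomic_inflation(p_mlm),
        "lambda_naive": mlmgwas.genomic_inflation(p_naive),
        "frac_sig_mlm": float((p_mlm < 0.05).mean()),
    }


def qtl_power(seed: int, effect_frac: float = 0.10) -> dict:
    """Whether a planted QTL attains the scan maximum of -log10 p.

    Uses the same 10-chromosome, 1500-marker genome as the hotspot-recovery
    study; the scan runs on across-year accession means.
    """
    cfg = synthdata.SimConfig(
        n_accessions=300,
        n_chromosomes=10,
        markers_per_chrom=150,
        seed=seed,
        planted_qtls=[("chr02", 60.0, "yield", effect_frac)],
        h2_targets={"yield": 0.6},
    )
    panel = synthdata.simulate_genotypes(cfg)
    tab, truth = synthdata.simulate_phenotypes(panel, cfg)
    scan = mlmgwas.mlm_scan(
        panel, _acc_means(tab, "yield"), "yield", mlmgwas.GwasConfig(cofactors=[])
    )
    top = scan.loc[scan["neglog10p"].idxmax()]
    qmk = truth.qtl_positions[0][4]
    return {
        "top_is_planted": bool(top["marker_id"] == qmk),
        "qtl_neglog10p": float(scan.loc[scan["marker_id"] == qmk, "neglog10p"].iloc[0]),
    }


def h2_recovery(target_h2: float, seed: int) -> dict:
    """One replicate of Knapp H2 and sigma2_G recovery at a target value."""
    cfg = synthdata.SimConfig(
        n_accessions=200,
        n_chromosomes=2,
        markers_per_chrom=100,
        seed=seed,
        h2_targets={"yield": target_h2},
    )
    panel = synthdata.simulate_genotypes(cfg)
    tab, truth = synthdata.simulate_phenotypes(panel, cfg)
    vc = quantpheno.fit_mixed_model(tab, "yield")
    return {
        "h2_hat": quantpheno.heritability(vc),
        "sigma2_G_hat": vc.sigma2_G,
        "sigma2_G_true": truth.variance_components["yield"]["sigma2_G"],
    }


def hotspot_recovery(seed: int, effect_frac: float = 0.15) -> dict:
    """Full-pipeline recovery of a planted 2-trait x 2-year QTL cluster.

    Returns how many retained hotspots contain the planted position, how
    many sit on the planted chromosome at all, and how many arise on the
    nine chromosomes with no planted signal.
    """
    cfg = synthdata.SimConfig(
        n_accessions=300,
        n_chromosomes=10,
        markers_per_chrom=150,
        seed=seed,
        years=["Y1", "Y2"],
        planted_qtls=[
            ("chr01", 50.0, "yield", effect_frac),
            ("chr01", 50.0, "ndvi", effect_frac),
        ],
        h2_targets={"yield": 0.6, "ndvi": 0.6},
    )
    panel = synthdata.simulate_genotypes(cfg)
    tab, truth = synthdata.simulate_phenotypes(panel, cfg)
    gcfg = mlmgwas.GwasConfig(cofactors=[])
    K = mlmgwas.kinship(panel)
    scans = [
        mlmgwas.mlm_scan(
            panel, _acc_means(tab, trait, yr), trait, gcfg, environment=yr, K=K
        )
        for trait in ("yield", "ndvi")
        for yr in ("Y1", "Y2")
    ]
    allscan = pd.concat(scans, ignore_index=True)
    mtas = allscan[allscan["neglog10p"] > gcfg.suggestive_threshold].reset_index(
        drop=True
    )
    chroms = cfg.chrom_names()
    ld = {c: hotspots.ChromLDProfile(c, cfg.ld_decay(c)) for c in chroms}
    profiles = hotspots.overview_index(
        mtas, ld, {c: cfg.map_length(c) for c in chroms}, nbE=len(scans)
    )
    peaks = {c: hotspots.call_peaks(p) for c, p in profiles.items()}
    hs = hotspots.merge_to_hotspots(peaks, mtas, ld, panel.map)
    kept, excluded = hotspots.filter_hotspots(
        hs, {c: cfg.centromere(c) for c in chroms}
    )
    planted_cm = truth.qtl_positions[0][1]
    containing = [
        h
        for h in kept
        if h.chromosome == "chr01" and h.left_cm <= planted_cm <= h.right_cm
    ]
    return {
        "n_retained": len(kept),
        "n_containing_planted": len(containing),
        "n_on_planted_chrom": sum(1 for h in kept if h.chromosome == "chr01"),
        "n_on_empty_chroms": sum(1 for h in kept if h.chromosome != "chr01"),
        "n_excluded": len(excluded),
    }
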