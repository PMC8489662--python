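"""Synthetic data generator for a structured wheat association panel.

Everything the pipeline consumes can be produced here with known ground
truth: a biallelic SNP panel with subpopulation structure and map-consistent
linkage disequilibrium, genetic (cM) and collinear physical (bp) maps over
21 chromosomes, multi-year augmented-design plot phenotypes with planted
QTLs, and four-band plot reflectances tied to a heritable canopy variable.

Model sketch
------------
* Allele frequencies follow a Balding–Nichols model: an ancestral frequency
  per marker, with subpopulation frequencies drawn from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` at the configured FST.
* Within-chromosome LD arises from an ancestral-haplotype mosaic: each
  subpopulation carries a pool of founder haplotypes, and every accession
  haplotype is a mosaic of founders with switch points at rate
  ``1/ld_decay_cm`` per cM, so allele correlation decays approximately as
  ``exp(-d / ld_decay_cm)``.
* Phenotypes per year: ``y = mu + year + sum_q beta_q * dosage_q +
  g_polygenic + (g x year) + row + column + residual`` on an augmented
  row x column layout with two replicated checks at the configured
  checks-to-test ratio.
* Reflectances mix a bare-soil and a dense-canopy spectrum linearly in a
  latent canopy variable that loads on the accession's genetic value, so
  NDVI is heritable and increases with canopy.

All randomness flows from ``SimConfig.seed`` through independent
``numpy`` ``SeedSequence`` children, so a seed fixes every artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GenotypePanel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "WHEAT_CHROMOSOMES",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_reflectance",
    "reflectance_from_canopy",
]

#: hexaploid wheat chromosome names, map order
WHEAT_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")

# endmember reflectances (green, red, rededge, nir): bare soil vs dense canopy
_SOIL = np.array([0.14, 0.18, 0.22, 0.26])
_CANOPY = np.array([0.09, 0.04, 0.30, 0.55])

STAGE_CANOPY_SCALE = {"anthesis": 1.0, "postanthesis": 0.6}


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate a Mediterranean bread-wheat panel: 354 accessions in
    six genetic subpopulations, 21 chromosomes, three trial years with an
    augmented design (two checks, checks:tests 1:4), marker missingness
    well under the 25% QC bound and a 5% MAF floor.
    """

    n_accessions: int = 354
    n_subpops: int = 6
    fst: float = 0.2
    n_chromosomes: int = 21
    markers_per_chrom: int = 200
    map_length_cm: float | dict = 150.0
    chrom_length_bp: int | dict = 600_000_000
    ld_decay_cm: float | dict = 5.0
    centromere_cm: float | dict = 75.0
    planted_qtls: list = field(default_factory=list)  # (chrom, cM, trait, var frac)
    years: list = field(default_factory=lambda: ["2016", "2017", "2018"])
    h2_targets: dict = field(default_factory=lambda: {"yield": 0.9})
    check_ratio: float = 0.25
    reps_per_accession: int = 1
    residual_frac: float = 0.10  # plot residual variance / Knapp total
    rowcol_frac: float = 0.05  # row and column variance, each / Knapp total
    ge_share: float = 0.5  # share of (1 - h2) assigned to GxE (rest to year)
    # founder-pool size per subpopulation; pool drift adds ~1/(2*n_founders)
    # of spurious differentiation on top of fst, so keep it large
    n_founders: int = 200
    missing_rate: float = 0.05
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_accessions <= 0 or self.n_chromosomes <= 0 or self.markers_per_chrom <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.missing_rate <= 0.25:
            raise ValueError("missing_rate must lie in [0, 0.25]")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        for trait, h2 in self.h2_targets.items():
            if not 0 <= h2 <= 1:
                raise ValueError(f"h2_target for {trait!r} outside [0, 1]")
            planted = sum(q[3] for q in self.planted_qtls if q[2] == trait)
            if planted > h2 + 1e-12:
                raise ValueError(
                    f"planted QTL variance for {trait!r} ({planted}) exceeds its h2 target ({h2})"
                )
        for c in self.chrom_names():
            if not 0 < self._per_chrom(self.centromere_cm, c) < self._per_chrom(
                self.map_length_cm, c
            ):
                raise ValueError(f"centromere for {c} outside (0, map length)")

    def chrom_names(self) -> list[str]:
        if self.n_chromosomes == 21:
            return list(WHEAT_CHROMOSOMES)
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @staticmethod
    def _per_chrom(value, chrom):
        return value[chrom] if isinstance(value, dict) else value

    def map_length(self, chrom) -> float:
        return float(self._per_chrom(self.map_length_cm, chrom))

    def bp_length(self, chrom) -> int:
        return int(self._per_chrom(self.chrom_length_bp, chrom))

    def ld_decay(self, chrom) -> float:
        return float(self._per_chrom(self.ld_decay_cm, chrom))

    def centromere(self, chrom) -> float:
        return float(self._per_chrom(self.centromere_cm, chrom))


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    qtl_positions: list  # (chrom, cM, trait, effect fraction, marker_id)
    variance_components: dict  # trait -> dict(sigma2_G, sigma2_E, sigma2_GE)
    subpop_assignment: dict  # accession -> subpopulation label
    genetic_values: pd.DataFrame | None = None  # accession x trait

    def to_json(self, path) -> None:
        payload = {
            "qtl_positions": [list(q) for q in self.qtl_positions],
            "variance_components": self.variance_components,
            "subpop_assignment": self.subpop_assignment,
        }
        if self.genetic_values is not None:
            payload["genetic_values"] = self.genetic_values.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rngs(cfg: SimConfig, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]


def _bp_from_cm(cm: np.ndarray, cfg: SimConfig, chrom: str) -> np.ndarray:
    """Monotone piecewise-linear bp(cM) with suppressed recombination around
    the centromere: the pericentromeric 10% of the genetic map covers half of
    the physical chromosome."""
    L = cfg.map_length(chrom)
    Lbp = cfg.bp_length(chrom)
    cent = cfg.centromere(chrom)
    w = 0.05 * L
    lo, hi = max(cent - w, 0.0), min(cent + w, L)
    knots_cm = np.array([0.0, lo, hi, L])
    arm_cm = (lo - 0.0) + (L - hi)
    # arms share half the physical length proportionally to their cM span
    arm_bp = 0.5 * Lbp
    knots_bp = np.array(
        [0.0, arm_bp * lo / arm_cm, arm_bp * lo / arm_cm + 0.5 * Lbp, Lbp]
    )
    return np.interp(cm, knots_cm, knots_bp)


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a structured biallelic dosage panel with map-consistent LD."""
    rng = _rngs(cfg)[0]
    chroms = cfg.chrom_names()
    n = cfg.n_accessions
    subpop = np.arange(n) % cfg.n_subpops  # balanced assignment
    F = cfg.fst
    a_shape = (1.0 - F) / F

    marker_ids, map_rows, dosage_blocks = [], [], []
    for chrom in chroms:
        L = cfg.map_length(chrom)
        m = cfg.markers_per_chrom
        cm = np.sort(rng.uniform(0.0, L, size=m))
        bp = np.round(_bp_from_cm(cm, cfg, chrom)).astype(np.int64)
        bp = np.maximum.accumulate(bp)  # guard rounding ties

        # Balding-Nichols frequencies and founder haplotype pools; founder
        # haplotypes carry internal block structure (allele copied from the
        # previous marker with probability exp(-gap/ld_decay)), which is what
        # makes founder-segment sharing translate into marker-marker LD
        p_anc = rng.uniform(0.1, 0.9, size=m)
        # Balding-Nichols subpopulation frequencies, autocorrelated along the
        # chromosome through a Gaussian copula so a subpopulation's deviation
        # from the ancestral frequency varies smoothly with map position
        # (neighbouring markers share their differentiation)
        gap_keep = np.exp(-np.diff(cm) / (2.0 * cfg.ld_decay(chrom)))
        z = np.empty((cfg.n_subpops, m))
        z[:, 0] = rng.standard_normal(cfg.n_subpops)
        for j in range(1, m):
            rho = gap_keep[j - 1]
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(
                cfg.n_subpops
            )
        from scipy.stats import beta as beta_dist, norm as norm_dist

        p_sub = beta_dist.ppf(
            norm_dist.cdf(z), p_anc[None, :] * a_shape, (1 - p_anc[None, :]) * a_shape
        )
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
        # founder haplotypes: threshold a per-founder Gaussian AR(1) latent
        # process at the subpopulation frequency, so every marker keeps the
        # exact Balding-Nichols marginal while alleles along a founder are
        # autocorrelated; founder-block and mosaic-switch processes each
        # decay at half-rate, so allele correlation decays ~exp(-d/ld)
        w = np.empty((cfg.n_subpops, cfg.n_founders, m))
        w[:, :, 0] = rng.standard_normal((cfg.n_subpops, cfg.n_founders))
        for j in range(1, m):
            rho = gap_keep[j - 1]
            w[:, :, j] = rho * w[:, :, j - 1] + np.sqrt(
                1 - rho**2
            ) * rng.standard_normal((cfg.n_subpops, cfg.n_founders))
        founders = (w < norm_dist.ppf(p_sub)[:, None, :]).astype(np.int8)

        # mosaic haplotypes: the founder identity along a haplotype is a
        # Markov jump process with switch rate 1/ld_decay_cm per cM, sampled
        # directly at the marker positions for all 2n haplotypes at once
        lam = 1.0 / (2.0 * cfg.ld_decay(chrom))
        n_hap = 2 * n
        sp_hap = np.repeat(subpop, 2)
        fid = np.empty((n_hap, m), dtype=np.int32)
        fid[:, 0] = rng.integers(0, cfg.n_founders, size=n_hap)
        stay_p = np.exp(-lam * np.diff(cm))
        for j in range(1, m):
            stay = rng.random(n_hap) < stay_p[j - 1]
            fresh = rng.integers(0, cfg.n_founders, size=n_hap)
            fid[:, j] = np.where(stay, fid[:, j - 1], fresh)
        cols = np.arange(m)[None, :]
        alleles = founders[sp_hap[:, None], fid, cols]
        dos = (alleles[0::2] + alleles[1::2]).astype(float)

        # missing-completely-at-random with a guaranteed per-marker cap
        if cfg.missing_rate > 0:
            rates = rng.uniform(0.0, cfg.missing_rate, size=m)
            for j, r in enumerate(rates):
                k = int(np.floor(r * n))
                if k:
                    dos[rng.choice(n, size=k, replace=False), j] = np.nan

        # enforce the MAF floor on the observed calls by redrawing failing
        # marker columns in the founder pools (the mosaic structure, hence
        # LD, is untouched; the missingness mask stays fixed)
        for _ in range(20):
            with np.errstate(invalid="ignore"):
                freq = np.nanmean(dos, axis=0) / 2.0
            maf = np.minimum(freq, 1.0 - freq)
            bad = np.flatnonzero(maf < cfg.maf_floor)
            if bad.size == 0:
                break
            p_new = rng.uniform(0.3, 0.7, size=(cfg.n_subpops, bad.size))
            founders[:, :, bad] = (
                rng.random((cfg.n_subpops, cfg.n_founders, bad.size))
                < p_new[:, None, :]
            ).astype(np.int8)
            alleles_bad = founders[sp_hap[:, None], fid[:, bad], bad[None, :]]
            redrawn = (alleles_bad[0::2] + alleles_bad[1::2]).astype(float)
            redrawn[np.isnan(dos[:, bad])] = np.nan
            dos[:, bad] = redrawn

        ids = [f"{chrom}_m{j:04d}" for j in range(m)]
        marker_ids.extend(ids)
        for j in range(m):
            map_rows.append((chrom, float(cm[j]), int(bp[j])))
        dosage_blocks.append(dos)

    dosages = np.hstack(dosage_blocks)

    accession_ids = [f"ACC{i:04d}" for i in range(n)]
    mp = pd.DataFrame(map_rows, columns=["chrom", "cm", "bp"], index=marker_ids)
    mp.index.name = "marker"
    panel = GenotypePanel(accession_ids, marker_ids, dosages, mp)
    panel.subpop = {a: f"SP{subpop[i] + 1}" for i, a in enumerate(accession_ids)}
    return panel


def _imputed_centered(panel: GenotypePanel) -> np.ndarray:
    d = panel.dosages.copy()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    return d - mu


def _snap_qtls(panel: GenotypePanel, planted: list, max_dist_cm: float = 5.0) -> list:
    """Snap each requested (chrom, cM) to the nearest mapped marker."""
    out = []
    for chrom, cm, trait, frac in planted:
        sub = panel.map[panel.map["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"planted QTL on unknown chromosome {chrom!r}")
        j = (sub["cm"] - cm).abs().idxmin()
        if abs(sub.loc[j, "cm"] - cm) > max_dist_cm:
            raise ValueError(
                f"no marker within {max_dist_cm} cM of planted QTL at {chrom}:{cm}"
            )
        out.append((chrom, float(sub.loc[j, "cm"]), trait, float(frac), j))
    return out


def simulate_phenotypes(
    panel: GenotypePanel, cfg: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-year augmented-design plot phenotypes with planted QTLs.

    Returns a tidy table with columns ``plot_id, accession_id, year, row,
    column, is_check, trait, value`` and the ground truth (QTL positions
    snapped to markers, generating variance components, subpopulations,
    per-accession genetic values).

    The Knapp-scale total (sigma2_G + sigma2_E + sigma2_GE) is 1 per trait:
    sigma2_G = h2 target, the remainder split between year and GxE by
    ``ge_share``; plot residual and row/column variances are additional
    fractions of that total.
    """
    rng = _rngs(cfg)[1]
    n = panel.n_accessions
    acc = panel.accession_ids
    qtls = _snap_qtls(panel, cfg.planted_qtls)
    Zc = _imputed_centered(panel)
    mpos = {m: i for i, m in enumerate(panel.marker_ids)}

    # layout: tests once (or reps) per year, two replicated checks interleaved
    check_accs = acc[:2]
    n_test_plots = n * cfg.reps_per_accession
    n_check_plots = max(int(round(cfg.check_ratio * n_test_plots)), 2)
    plots_acc = list(np.repeat(acc, cfg.reps_per_accession)) + [
        check_accs[i % 2] for i in range(n_check_plots)
    ]
    is_check = [False] * n_test_plots + [True] * n_check_plots
    order = rng.permutation(len(plots_acc))
    plots_acc = [plots_acc[i] for i in order]
    is_check = [is_check[i] for i in order]
    n_plots = len(plots_acc)
    n_cols = int(np.ceil(np.sqrt(n_plots)))
    rows_ix = [f"R{i // n_cols + 1:02d}" for i in range(n_plots)]
    cols_ix = [f"C{i % n_cols + 1:02d}" for i in range(n_plots)]

    truth_vc, gvals = {}, {}
    records = []
    for trait, h2 in cfg.h2_targets.items():
        s2g = h2
        s2e = (1.0 - h2) * (1.0 - cfg.ge_share)
        s2ge = (1.0 - h2) * cfg.ge_share
        s2res = cfg.residual_frac
        s2rc = cfg.rowcol_frac
        truth_vc[trait] = {"sigma2_G": s2g, "sigma2_E": s2e, "sigma2_GE": s2ge}

        # genetic values: planted QTL effects + polygenic background
        g = np.zeros(n)
        planted_frac = 0.0
        for chrom, cm, t, frac, mid in qtls:
            if t != trait:
                continue
            x = Zc[:, mpos[mid]]
            v = x.var()
            if v == 0:
                raise ValueError(f"planted QTL marker {mid} is monomorphic")
            g += np.sqrt(frac / v) * x
            planted_frac += frac
        poly_var = max(s2g - planted_frac, 0.0)
        if poly_var > 0:
            w = rng.standard_normal(panel.n_markers)
            gp = Zc @ w
            # orthogonalize the polygenic part to the planted QTL dosages so
            # each planted effect realizes exactly its configured variance
            qcols = [mpos[mid] for c, _, t, _, mid in qtls if t == trait]
            if qcols:
                Xq = Zc[:, qcols]
                coef, *_ = np.linalg.lstsq(Xq, gp, rcond=None)
                gp = gp - Xq @ coef
            if gp.var() > 0:
                g += gp / gp.std() * np.sqrt(poly_var)
        gvals[trait] = g
        gmap = dict(zip(acc, g))

        year_eff = rng.normal(0.0, np.sqrt(s2e), size=len(cfg.years))
        ge = rng.normal(0.0, np.sqrt(s2ge), size=(n, len(cfg.years)))
        gemap = {a: ge[i] for i, a in enumerate(acc)}
        for yi, year in enumerate(cfg.years):
            row_eff = {
                r: rng.normal(0.0, np.sqrt(s2rc)) for r in sorted(set(rows_ix))
            }
            col_eff = {
                c: rng.normal(0.0, np.sqrt(s2rc)) for c in sorted(set(cols_ix))
            }
            resid = rng.normal(0.0, np.sqrt(s2res), size=n_plots)
            for k in range(n_plots):
                a = plots_acc[k]
                records.append(
                    (
                        f"{year}_P{k:04d}",
                        a,
                        str(year),
                        rows_ix[k],
                        cols_ix[k],
                        is_check[k],
                        trait,
                        gmap[a]
                        + year_eff[yi]
                        + gemap[a][yi]
                        + row_eff[rows_ix[k]]
                        + col_eff[cols_ix[k]]
                        + resid[k],
                    )
                )

    tab = pd.DataFrame(
        records,
        columns=list(
            (
                "plot_id",
                "accession_id",
                "year",
                "row",
                "column",
                "is_check",
                "trait",
                "value",
            )
        ),
    )
    subpop = getattr(panel, "subpop", {a: "SP1" for a in acc})
    truth = GroundTruth(
        qtl_positions=qtls,
        variance_components=truth_vc,
        subpop_assignment=dict(subpop),
        genetic_values=pd.DataFrame(gvals, index=acc),
    )
    return tab, truth


def reflectance_from_canopy(canopy: np.ndarray, stage: str) -> np.ndarray:
    """Deterministic four-band reflectance (green, red, rededge, nir) for a
    canopy fraction in [0, 1].  NIR increases and red decreases with canopy."""
    if stage not in STAGE_CANOPY_SCALE:
        raise ValueError(f"unknown stage {stage!r}")
    c = np.clip(np.asarray(canopy, dtype=float), 0.0, 1.0) * STAGE_CANOPY_SCALE[stage]
    return _SOIL[None, :] + c[:, None] * (_CANOPY - _SOIL)[None, :]


def simulate_reflectance(
    panel: GenotypePanel,
    truth: GroundTruth,
    stage: str,
    h2_canopy: float = 0.5,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Per-plot band reflectances tied to a heritable latent canopy.

    The latent canopy variable loads on the accession's genetic value with
    heritability ``h2_canopy``; a ``canopy`` column in the ground-truth
    genetic values is used when present, else the first trait's values.
    One plot per accession is emitted; the latent canopy is included so
    recovery tests can see the ground truth.
    """
    if stage not in STAGE_CANOPY_SCALE:
        raise ValueError(f"unknown stage {stage!r}")
    gv = truth.genetic_values
    if gv is None or gv.empty:
        raise ValueError("ground truth carries no genetic values")
    col = "canopy" if "canopy" in gv.columns else gv.columns[0]
    g = gv[col].reindex(panel.accession_ids).to_numpy()
    g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([8751, seed_offset]))
    noise = rng.standard_normal(len(g))
    latent = np.sqrt(h2_canopy) * g + np.sqrt(max(1 - h2_canopy, 0.0)) * noise
    # squash to a canopy fraction; mean cover ~0.7 at anthesis
    canopy = 1.0 / (1.0 + np.exp(-(0.8 * latent + 0.8)))
    bands = reflectance_from_canopy(canopy, stage)
    return pd.DataFrame(
        {
            "plot_id": [f"{stage[:2].upper()}_{a}" for a in panel.accession_ids],
            "accession_id": panel.accession_ids,
            "stage": stage,
            "green": bands[:, 0],
            "red": bands[:, 1],
            "rededge": bands[:, 2],
            "nir": bands[:, 3],
            "canopy": canopy,
        }
    )
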