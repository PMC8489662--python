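"""Mixed-linear-model association scan with population-structure control.

The scan fits, for each marker,

    y = marker + PCs + cofactors + u + e,    cov(u) = sigma2_g * K

with K a VanRaden genomic relationship matrix and the leading principal
components of the genotype matrix as fixed covariates (the PCA + K model).
Variance components are estimated once on the null model (no marker) and
reused for every marker test — the population-parameters-previously-
determined (P3D) shortcut — after which each marker is a generalized
least-squares t-test in the rotated (whitened) space.

A naive single-marker OLS scan (no structure control) is provided for
calibration comparisons: under strong structure its genomic inflation
factor exceeds the mixed model's, which is the reason to use PCA + K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markers import GenotypePanel

__all__ = [
    "GwasConfig",
    "MTA_COLUMNS",
    "kinship",
    "genotype_pcs",
    "mlm_scan",
    "naive_scan",
    "thresholds",
    "bh_threshold",
    "genomic_inflation",
]

#: column contract for marker-trait-association tables
MTA_COLUMNS = (
    "marker_id",
    "chrom",
    "cm",
    "bp",
    "trait",
    "environment",
    "neglog10p",
    "pve",
    "effect",
)


@dataclass
class GwasConfig:
    """Scan settings: six PCs, anthesis-date cofactor, suggestive threshold
    of -log10 p = 3 and a corrected threshold from the LD-based effective
    marker count."""

    n_pcs: int = 6
    cofactors: list[str] = field(default_factory=lambda: ["anthesis"])
    suggestive_threshold: float = 3.0
    fdr_alpha: float = 0.05
    effective_markers: int = 3696
    seed: int = 0

    def __post_init__(self):
        if self.suggestive_threshold <= 0 or not 0 < self.fdr_alpha < 1:
            raise ValueError("thresholds must be positive and alpha in (0,1)")


def _imputed(panel: GenotypePanel) -> np.ndarray:
    d = panel.dosages.copy()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    return d


def kinship(panel: GenotypePanel) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    K = Z Z' / (2 * sum p(1-p)) with Z the mean-imputed dosage matrix
    centered at 2p.  Symmetric, positive semi-definite, diagonal near
    1 + inbreeding, invariant to marker order.
    """
    d = _imputed(panel)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; kinship undefined")
    Z = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = Z @ Z.T / denom
    return pd.DataFrame(K, index=panel.accession_ids, columns=panel.accession_ids)


def genotype_pcs(panel: GenotypePanel, n_pcs: int) -> pd.DataFrame:
    """Leading principal components of the centered, mean-imputed dosages."""
    Z = _imputed(panel)
    Z = Z - Z.mean(axis=0)
    if n_pcs >= panel.n_accessions:
        raise ValueError("n_pcs must be < n_accessions")
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        pcs, index=panel.accession_ids, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )


def _null_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Profile REML of y = Xb + u + e with cov(u) = sg*K, via the spectral
    decomposition of K.  Returns (eigvecs, eigvals, delta = se/sg)."""
    n, p = X.shape
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        r = yr - Xr @ beta
        rss = float(np.sum(r * r / w))
        sg = rss / (n - p)
        _, ld_XtWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(sg) + np.sum(np.log(w)) + ld_XtWX + (n - p))
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    return U, lam, float(np.exp(res.x))


def _prepare_fixed(
    panel: GenotypePanel,
    phenos: pd.DataFrame,
    trait: str,
    cfg: GwasConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    common = [a for a in panel.accession_ids if a in phenos.index]
    sub = phenos.loc[common]
    mask = sub[trait].notna()
    cof_names = [c for c in cfg.cofactors if c != trait and c in sub.columns]
    for c in cof_names:
        mask &= sub[c].notna()
    common = [a for a, ok in zip(common, mask) if ok]
    if len(common) < cfg.n_pcs + len(cof_names) + 5:
        raise ValueError(f"too few accessions with phenotype {trait!r}")
    y = phenos.loc[common, trait].to_numpy(dtype=float)
    cols = [np.ones(len(common))]
    pcs = genotype_pcs(panel, cfg.n_pcs).loc[common].to_numpy()
    cols.append(pcs)
    for c in cof_names:
        cols.append(phenos.loc[common, c].to_numpy(dtype=float)[:, None])
    X = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    # drop collinear fixed columns (e.g. a PC aliasing a cofactor)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
    if not keep.all():
        raise ValueError(
            f"singular fixed-effect design for trait {trait!r}: "
            f"{int((~keep).sum())} collinear column(s)"
        )
    return y, X, common


def _marker_tests(
    yt: np.ndarray, Xt: np.ndarray, Gt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker t-tests of whitened y on whitened markers,
    residualized on the whitened fixed design.  Returns (beta, pvals, pve,
    ok-mask)."""
    n, p0 = Xt.shape
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)
    RG = Gt - Q @ (Q.T @ Gt)
    ss_m = np.einsum("ij,ij->j", RG, RG)
    ok = ss_m > 1e-12
    df = n - p0 - 1
    beta = np.zeros(Gt.shape[1])
    tstat = np.zeros(Gt.shape[1])
    xy = ry @ RG
    beta[ok] = xy[ok] / ss_m[ok]
    ss_y = float(ry @ ry)
    rss = ss_y - beta**2 * ss_m
    rss = np.clip(rss, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / ss_m)
        tstat[ok] = beta[ok] / se[ok]
    pvals = np.ones(Gt.shape[1])
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pve = np.zeros(Gt.shape[1])
    pve[ok] = tstat[ok] ** 2 / (tstat[ok] ** 2 + df)
    return beta, pvals, pve, ok


def mlm_scan(
    panel: GenotypePanel,
    phenos: pd.DataFrame,
    trait: str,
    cfg: GwasConfig,
    environment: str = "mean",
    K: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """PCA + K mixed-model scan for one trait in one environment.

    ``phenos`` is an accession-indexed DataFrame holding the trait column and
    any cofactor columns (a cofactor equal to the scanned trait is skipped).
    Null-model variance components are estimated once and reused per marker
    (P3D).  All markers are emitted — thresholding is a downstream filter;
    zero-variance markers are skipped with ``pve = NaN``.
    """
    y, X, common = _prepare_fixed(panel, phenos, trait, cfg)
    Km = (kinship(panel) if K is None else K).loc[common, common].to_numpy()
    U, lam, delta = _null_reml(y, X, Km)
    w = np.sqrt(lam + delta)
    yt = (U.T @ y) / w
    Xt = (U.T @ X) / w[:, None]
    rows = {a: i for i, a in enumerate(panel.accession_ids)}
    sel = [rows[a] for a in common]
    G = _imputed(panel)[sel]
    Gt = (U.T @ G) / w[:, None]
    beta, pvals, pve, ok = _marker_tests(yt, Xt, Gt)
    out = pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chrom": panel.map["chrom"].to_numpy(),
            "cm": panel.map["cm"].to_numpy(),
            "bp": panel.map["bp"].to_numpy(),
            "trait": trait,
            "environment": environment,
            "neglog10p": -np.log10(pvals),
            "pve": np.where(ok, pve, np.nan),
            "effect": np.where(ok, beta, np.nan),
        }
    )
    out.loc[~ok, "neglog10p"] = np.nan
    return out


def naive_scan(
    panel: GenotypePanel,
    phenos: pd.DataFrame,
    trait: str,
    environment: str = "mean",
) -> pd.DataFrame:
    """Single-marker OLS scan with no structure control (calibration foil)."""
    common = [a for a in panel.accession_ids if a in phenos.index]
    common = [a for a in common if pd.notna(phenos.loc[a, trait])]
    y = phenos.loc[common, trait].to_numpy(dtype=float)
    X = np.ones((len(common), 1))
    rows = {a: i for i, a in enumerate(panel.accession_ids)}
    G = _imputed(panel)[[rows[a] for a in common]]
    beta, pvals, pve, ok = _marker_tests(y, X, G)
    out = pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chrom": panel.map["chrom"].to_numpy(),
            "cm": panel.map["cm"].to_numpy(),
            "bp": panel.map["bp"].to_numpy(),
            "trait": trait,
            "environment": environment,
            "neglog10p": -np.log10(pvals),
            "pve": np.where(ok, pve, np.nan),
            "effect": np.where(ok, beta, np.nan),
        }
    )
    out.loc[~ok, "neglog10p"] = np.nan
    return out


def thresholds(cfg: GwasConfig) -> tuple[float, float]:
    """(suggestive, corrected) -log10 p thresholds.

    The corrected threshold is -log10(alpha / M_eff) on the LD-based
    effective marker count (for alpha = 0.05 and M_eff = 3696 this gives
    4.869; a data-dependent Benjamini-Hochberg cut is available separately
    via :func:`bh_threshold`).
    """
    if cfg.effective_markers <= 0:
        raise ValueError("effective_markers must be positive")
    return (
        float(cfg.suggestive_threshold),
        float(-np.log10(cfg.fdr_alpha / cfg.effective_markers)),
    )


def bh_threshold(pvals: np.ndarray, alpha: float = 0.05) -> float:
    """Data-dependent Benjamini-Hochberg cut as a -log10 p threshold.

    Returns the -log10 of the largest p-value passing the BH step-up rule,
    or +inf when nothing passes.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    passing = p <= alpha * np.arange(1, m + 1) / m
    if not passing.any():
        return float("inf")
    return float(-np.log10(p[np.flatnonzero(passing).max()]))


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor lambda: median chi-square over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
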