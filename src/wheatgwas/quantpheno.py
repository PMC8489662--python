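"""Multi-year phenotype modelling: REML variance components, BLUPs,
broad-sense heritability and ANOVA variance partitioning.

The field design is an augmented layout: unreplicated test entries plus two
replicated check cultivars arranged in a row x column grid, repeated over
years.  The per-environment model treats check cultivars as fixed and rows,
columns and accessions as random; variance components are estimated by
EM-REML (see :mod:`wheatgwas._reml`).

Broad-sense heritability across years follows the three-component form

    H2 = sigma2_G / (sigma2_G + sigma2_E + sigma2_GE)

with sigma2_G the genotypic variance, sigma2_E the year variance and
sigma2_GE the genotype-by-year interaction variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._reml import em_reml

__all__ = [
    "PHENOTYPE_COLUMNS",
    "VarianceComponents",
    "fit_mixed_model",
    "heritability",
    "variance_partition",
    "trait_correlations",
]

#: tidy phenotype table contract (one row per plot per trait per year)
PHENOTYPE_COLUMNS = (
    "plot_id",
    "accession_id",
    "year",
    "row",
    "column",
    "is_check",
    "trait",
    "value",
)


@dataclass
class VarianceComponents:
    """REML variance components and accession BLUPs for one trait."""

    sigma2_G: float
    sigma2_E: float
    sigma2_GE: float
    sigma2_row: float
    sigma2_col: float
    sigma2_residual: float
    blups: dict[str, float]
    loglik: float = float("nan")
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_G": self.sigma2_G,
                "sigma2_E": self.sigma2_E,
                "sigma2_GE": self.sigma2_GE,
                "sigma2_row": self.sigma2_row,
                "sigma2_col": self.sigma2_col,
                "sigma2_residual": self.sigma2_residual,
            }
        )


def _indicator(levels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(levels)
    Z = np.zeros((len(levels), len(cats.categories)))
    Z[np.arange(len(levels)), cats.codes] = 1.0
    return Z, list(cats.categories)


def _spatial_adjust(dy: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Row/column adjustment for one year.

    When enough check plots are present, row and column effects are
    estimated by REML on *half* of the replicated check plots — the
    classical augmented-design adjustment — and subtracted from every plot.
    The held-out check half then gives an honest estimate of the per-plot
    noise that the (equally held-out) test plots carry after adjustment:
    plot residual plus unremoved spatial variance plus adjustment error.
    Without checks the fit uses all plots with accession as an extra random
    term and the REML residual stands in for the plot noise.

    Returns (adjusted values indexed like ``dy``, holdout sum of squares,
    holdout degrees of freedom).
    """
    checks = dy[dy["is_check"]]
    use_checks = checks["accession_id"].nunique() >= 1 and len(checks) >= 16
    if use_checks:
        fit_half = checks.iloc[::2]
        holdout = checks.iloc[1::2]
        sub = fit_half
        X = pd.get_dummies(sub["accession_id"], dtype=float).to_numpy()
        Zfac = {}
    else:
        sub = dy
        X = np.ones((len(sub), 1))
        Za, _ = _indicator(sub["accession_id"])
        Zfac = {"accession": Za}
    Zr, rows = _indicator(sub["row"])
    Zc, cols = _indicator(sub["column"])
    Zfac.update({"row": Zr, "column": Zc})
    res = em_reml(sub["value"].to_numpy(), X, Zfac)

    row_eff = dict(zip(rows, res.blups["row"]))
    col_eff = dict(zip(cols, res.blups["column"]))
    adj = dy["value"] - dy["row"].map(row_eff).fillna(0.0) - dy["column"].map(
        col_eff
    ).fillna(0.0)
    if use_checks:
        held = adj.loc[holdout.index]
        groups = holdout["accession_id"]
        ss = dof = 0.0
        for _, vals in held.groupby(groups):
            if len(vals) >= 2:
                ss += ((vals - vals.mean()) ** 2).sum()
                dof += len(vals) - 1
        if dof == 0:
            ss, dof = res.sigma2_residual, 1.0
    else:
        ss, dof = res.sigma2_residual, 1.0
    return adj, float(ss), float(dof)


def fit_mixed_model(
    tab: pd.DataFrame,
    trait: str,
    mode: str = "two_stage",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VarianceComponents:
    """Estimate genetic, year and genotype-by-year variances for one trait.

    ``mode="two_stage"`` (default) mirrors per-environment fitting followed
    by a cross-year model: within each year a check-based REML fit estimates
    row/column effects and the plot residual variance; the spatially adjusted
    accession-year means then enter a two-way random model
    ``value ~ accession + year`` whose residual carries GE plus the residual
    leak, which is removed by a method-of-moments correction (floored at 0).

    ``mode="pooled"`` fits the full plot-level model in one EM-REML run with
    check cultivars fixed and accession, year, accession x year, row-in-year
    and column-in-year random.  It is exact but costly for large layouts.
    """
    d = tab[tab["trait"] == trait].copy()
    if d.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    if d["year"].nunique() < 2:
        raise ValueError("need >= 2 years")
    if d["accession_id"].nunique() < 2:
        raise ValueError("need >= 2 accessions")
    if mode == "two_stage":
        return _fit_two_stage(d, tol=tol, max_iter=max_iter)
    if mode == "pooled":
        return _fit_pooled(d, tol=tol, max_iter=max_iter)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_two_stage(d: pd.DataFrame, tol: float, max_iter: int) -> VarianceComponents:
    adj_parts, ss_tot, dof_tot = [], 0.0, 0.0
    for _, dy in d.groupby("year", observed=True):
        adj, ss, dof = _spatial_adjust(dy)
        dd = dy[["accession_id", "year"]].copy()
        dd["adj"] = adj
        adj_parts.append(dd)
        ss_tot += ss
        dof_tot += dof
    adj_all = pd.concat(adj_parts)
    # effective per-plot noise after spatial adjustment (plot residual plus
    # unremoved spatial variance plus adjustment error), from held-out checks
    sigma2_plot = ss_tot / max(dof_tot, 1.0)

    cell = (
        adj_all.groupby(["accession_id", "year"], observed=True)["adj"]
        .agg(["mean", "size"])
        .reset_index()
    )
    y = cell["mean"].to_numpy()
    Za, acc_levels = _indicator(cell["accession_id"])
    Zy, _ = _indicator(cell["year"])
    X = np.ones((len(cell), 1))
    res = em_reml(y, X, {"accession": Za, "year": Zy}, tol=tol, max_iter=max_iter)

    # the cell-level residual is sigma2_GE + sigma2_plot * mean(1/reps)
    leak = sigma2_plot * float(np.mean(1.0 / cell["size"]))
    sigma2_ge = max(res.sigma2_residual - leak, 0.0)

    blups = dict(zip(acc_levels, res.blups["accession"]))
    return VarianceComponents(
        sigma2_G=res.sigma2["accession"],
        sigma2_E=res.sigma2["year"],
        sigma2_GE=sigma2_ge,
        sigma2_row=float("nan"),
        sigma2_col=float("nan"),
        sigma2_residual=sigma2_plot,
        blups=blups,
        loglik=res.loglik,
        loglik_trace=res.loglik_trace,
        converged=res.converged,
        n_iter=res.n_iter,
    )


def _fit_pooled(d: pd.DataFrame, tol: float, max_iter: int) -> VarianceComponents:
    d = d.reset_index(drop=True)
    check_ids = sorted(d.loc[d["is_check"], "accession_id"].unique())
    X = np.ones((len(d), 1))
    if check_ids:
        dummies = pd.get_dummies(
            pd.Categorical(
                np.where(d["is_check"], d["accession_id"], "__test__"),
                categories=["__test__"] + check_ids,
            ),
            drop_first=True,
            dtype=float,
        ).to_numpy()
        X = np.hstack([X, dummies])

    test = d[~d["is_check"]] if check_ids else d
    Za_full, acc_levels = _indicator(
        pd.Categorical(d["accession_id"], categories=sorted(test["accession_id"].unique()))
    )
    Zy, _ = _indicator(d["year"])
    ge = d["accession_id"].astype(str) + "||" + d["year"].astype(str)
    Zge, _ = _indicator(ge)
    Zr, _ = _indicator(d["year"].astype(str) + "||" + d["row"].astype(str))
    Zc, _ = _indicator(d["year"].astype(str) + "||" + d["column"].astype(str))
    res = em_reml(
        d["value"].to_numpy(),
        X,
        {"accession": Za_full, "year": Zy, "ge": Zge, "row": Zr, "column": Zc},
        tol=tol,
        max_iter=max_iter,
    )
    blups = dict(zip(acc_levels, res.blups["accession"]))
    return VarianceComponents(
        sigma2_G=res.sigma2["accession"],
        sigma2_E=res.sigma2["year"],
        sigma2_GE=res.sigma2["ge"],
        sigma2_row=res.sigma2["row"],
        sigma2_col=res.sigma2["column"],
        sigma2_residual=res.sigma2_residual,
        blups=blups,
        loglik=res.loglik,
        loglik_trace=res.loglik_trace,
        converged=res.converged,
        n_iter=res.n_iter,
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = sigma2_G / (sigma2_G + sigma2_E + sigma2_GE)."""
    total = vc.sigma2_G + vc.sigma2_E + vc.sigma2_GE
    if total <= 0:
        raise ValueError("all variance components are zero")
    return vc.sigma2_G / total


def variance_partition(
    tab: pd.DataFrame, trait: str, grouping: dict[str, str]
) -> pd.Series:
    """Percent of ANOVA model sums of squares for Year, SP and Year x SP.

    ``grouping`` maps accession id to subpopulation label (admixed accessions
    may carry their own label).  Sums of squares are sequential (Type I) in
    the order Year, SP, Year x SP on accession-year means, expressed as
    percentages of their sum (so the three percentages add to 100).
    """
    d = tab[tab["trait"] == trait]
    if d.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    missing = set(d["accession_id"]) - set(grouping)
    if missing:
        raise ValueError(f"{len(missing)} accession(s) missing a subpopulation label")
    cell = (
        d.groupby(["accession_id", "year"], observed=True)["value"].mean().reset_index()
    )
    cell["sp"] = cell["accession_id"].map(grouping)
    year_span = cell.groupby("sp", observed=True)["year"].nunique()
    lonely = year_span[year_span < 2]
    if len(lonely):
        raise ValueError(
            f"subpopulation(s) present in a single year: {list(lonely.index)}"
        )
    fit = smf.ols("value ~ C(year) * C(sp)", data=cell).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    ss = aov.loc[["C(year)", "C(sp)", "C(year):C(sp)"], "sum_sq"]
    pct = 100.0 * ss / ss.sum()
    pct.index = ["Year", "SP", "Year x SP"]
    return pct


def trait_correlations(blup_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix among trait BLUP columns."""
    return blup_table.corr(method="pearson")
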