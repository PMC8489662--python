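"""QTL hotspot detection from marker-trait associations.

Each association is smeared along its chromosome as a Gaussian whose 95%
interval equals the chromosome's LD-decay distance CI:

    s = CI / 3.92        (3.92 = 2 * 1.96)

The per-cM *overview index* U is the total Gaussian location probability
falling in each 1-cM bin, divided by the number of experiments nbE, so the
map-wide mean of U equals nbQTL / (nbE * L) with L the total map length.
Peaks of U above a threshold (the map-wide mean, or a high multiple of it)
are merged into hotspots when their CI windows overlap; hotspots are then
filtered by the exclusion rules (centromere inside the interval, physical
CI over 35 Mb, support from a single year or a single trait) and given
physical intervals from the markers flanking their genetic bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ChromLDProfile",
    "OverviewProfile",
    "Hotspot",
    "mta_ci",
    "overview_index",
    "call_peaks",
    "merge_to_hotspots",
    "filter_hotspots",
    "physical_interval",
    "round_mb",
    "hotspot_table",
    "hotspots_to_bed",
]

CI_TO_SD = 3.92  # 95% two-sided normal interval width in SD units


@dataclass(frozen=True)
class ChromLDProfile:
    """Per-chromosome LD-decay distance used as the MTA confidence interval."""

    chromosome: str
    ci_cm: float

    def __post_init__(self):
        if self.ci_cm <= 0:
            raise ValueError("ci_cm must be positive")

    @property
    def s_cm(self) -> float:
        return self.ci_cm / CI_TO_SD


@dataclass
class OverviewProfile:
    """Overview-index values on a 1-cM grid for one chromosome."""

    chromosome: str
    positions: np.ndarray  # bin midpoints (cM)
    u: np.ndarray  # index value per bin
    mean_threshold: float = float("nan")  # map-wide mean of u
    high_threshold: float = float("nan")  # multiplier x mean


@dataclass
class Hotspot:
    id: str
    chromosome: str
    left_cm: float
    peak_cm: float
    right_cm: float
    member_mtas: pd.DataFrame
    traits: set = field(default_factory=set)
    years: set = field(default_factory=set)
    left_marker: str = ""
    right_marker: str = ""
    left_bp: int = 0
    right_bp: int = 0
    ci_mb: float = float("nan")
    max_neglog10p: float = float("nan")

    def __post_init__(self):
        if not self.left_cm <= self.peak_cm <= self.right_cm:
            raise ValueError("hotspot bounds must satisfy left <= peak <= right")


def mta_ci(
    cm: float, ld: ChromLDProfile, chrom_length_cm: float
) -> tuple[float, tuple[float, float]]:
    """Gaussian SD and CI bounds (cm +/- CI/2, clipped to the map) for one MTA."""
    s = ld.s_cm
    lo = max(cm - ld.ci_cm / 2.0, 0.0)
    hi = min(cm + ld.ci_cm / 2.0, chrom_length_cm)
    return s, (lo, hi)


def overview_index(
    mtas: pd.DataFrame,
    ld: dict[str, ChromLDProfile],
    map_lengths: dict[str, float],
    nbE: int,
) -> dict[str, OverviewProfile]:
    """Per-chromosome overview index on a 1-cM grid.

    For a bin centered at x, u(x) = (1/nbE) * sum_q [Phi((x+0.5-mu_q)/s_q)
    - Phi((x-0.5-mu_q)/s_q)] over MTAs q on the chromosome.  Thresholds
    (map-wide mean and 5x it by default via :func:`call_peaks` callers) are
    attached by this function: ``mean_threshold`` is the grand mean of u over
    all bins of all chromosomes.
    """
    if nbE < 1:
        raise ValueError("nbE must be >= 1")
    unknown = set(mtas["chrom"]) - set(map_lengths)
    if unknown:
        raise ValueError(f"MTAs on unmapped chromosome(s): {sorted(unknown)}")
    profiles: dict[str, OverviewProfile] = {}
    for chrom, L in map_lengths.items():
        if L <= 0:
            raise ValueError(f"zero map length for {chrom}")
        n_bins = int(np.ceil(L))
        centers = np.arange(n_bins) + 0.5
        u = np.zeros(n_bins)
        sub = mtas[mtas["chrom"] == chrom]
        if len(sub):
            if chrom not in ld:
                raise ValueError(f"no LD profile for chromosome {chrom}")
            s = ld[chrom].s_cm
            mu = sub["cm"].to_numpy()[:, None]
            upper = norm.cdf((centers[None, :] + 0.5 - mu) / s)
            lower = norm.cdf((centers[None, :] - 0.5 - mu) / s)
            u = (upper - lower).sum(axis=0) / nbE
        profiles[chrom] = OverviewProfile(chrom, centers, u)
    grand_mean = float(np.mean(np.concatenate([p.u for p in profiles.values()])))
    for p in profiles.values():
        p.mean_threshold = grand_mean
    return profiles


def call_peaks(
    profile: OverviewProfile,
    mean_mult: float = 1.0,
    high_mult: float = 5.0,
) -> pd.DataFrame:
    """Local maxima of u above tier thresholds.

    A peak is a strict local maximum (plateaus resolved to their midpoint
    bin) with u strictly above the tier threshold; tiers are ``mean``
    (mean_mult x map-wide mean) and ``high`` (high_mult x map-wide mean).
    Returns a DataFrame with columns cm, u, tier.
    """
    u = profile.u
    if u.size == 0:
        raise ValueError("empty overview profile")
    thr_mean = mean_mult * profile.mean_threshold
    thr_high = high_mult * profile.mean_threshold
    profile.high_threshold = thr_high

    # plateau-aware local maxima
    peaks = []
    i = 0
    n = u.size
    while i < n:
        j = i
        while j + 1 < n and u[j + 1] == u[i]:
            j += 1
        left_ok = i == 0 or u[i - 1] < u[i]
        right_ok = j == n - 1 or u[j + 1] < u[i]
        whole_map_plateau = i == 0 and j == n - 1
        if left_ok and right_ok and not whole_map_plateau and u[i] > 0:
            mid = (i + j) // 2
            peaks.append((profile.positions[mid], u[i]))
        i = j + 1
    rows = []
    for cm, val in peaks:
        if val > thr_high:
            rows.append((cm, val, "high"))
        elif val > thr_mean:
            rows.append((cm, val, "mean"))
    return pd.DataFrame(rows, columns=["cm", "u", "tier"])


def round_mb(delta_bp: int) -> float:
    """|bp difference| as Mb, rounded half-up to one decimal."""
    return float(
        (Decimal(int(abs(delta_bp))) / Decimal(10**6)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def physical_interval(left_bp: int, right_bp: int) -> float:
    """Physical CI length in Mb from the flanking-marker positions.

    The absolute difference is used: flanking markers may be stored in
    descending physical order where the genetic and physical maps run in
    opposite directions.
    """
    return round_mb(right_bp - left_bp)


def _flanking_markers(
    chrom_map: pd.DataFrame, lo_cm: float, hi_cm: float
) -> tuple[str, str]:
    """Nearest mapped markers at/outside the [lo_cm, hi_cm] bounds."""
    cm = chrom_map["cm"].to_numpy()
    left_cand = np.flatnonzero(cm <= lo_cm)
    right_cand = np.flatnonzero(cm >= hi_cm)
    left_ix = left_cand.max() if left_cand.size else int(np.argmin(np.abs(cm - lo_cm)))
    right_ix = (
        right_cand.min() if right_cand.size else int(np.argmax(cm))
    )
    return chrom_map.index[left_ix], chrom_map.index[right_ix]


def merge_to_hotspots(
    peaks_by_chrom: dict[str, pd.DataFrame],
    mtas: pd.DataFrame,
    ld: dict[str, ChromLDProfile],
    marker_map: pd.DataFrame,
    tier: str = "high",
) -> list[Hotspot]:
    """Merge peaks whose CI windows overlap into hotspots.

    Each peak gets a window peak +/- CI/2; overlapping windows on the same
    chromosome merge, the hotspot bounds being the union of the merged
    windows.  Member MTAs are all MTAs whose cM positions fall inside the
    bounds; a peak whose hotspot contains no MTA is a contradiction and
    raises.  Flanking markers are the nearest mapped markers at/outside the
    bounds; ids follow QTL<chrom>.<ordinal> in cM order per chromosome.
    """
    out: list[Hotspot] = []
    for chrom in sorted(peaks_by_chrom):
        pk = peaks_by_chrom[chrom]
        if tier == "high":
            pk = pk[pk["tier"] == "high"]
        if pk.empty:
            continue
        ci = ld[chrom].ci_cm
        windows = sorted(
            (row.cm - ci / 2.0, row.cm + ci / 2.0, row.cm, row.u)
            for row in pk.itertuples()
        )
        merged: list[list] = []
        for lo, hi, cm, uval in windows:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                if uval > merged[-1][3]:
                    merged[-1][2], merged[-1][3] = cm, uval
            else:
                merged.append([lo, hi, cm, uval])
        chrom_map = marker_map[marker_map["chrom"] == chrom].sort_values("cm")
        sub = mtas[mtas["chrom"] == chrom]
        for ordinal, (lo, hi, peak_cm, _uval) in enumerate(merged, start=1):
            lo = max(lo, 0.0)
            members = sub[(sub["cm"] >= lo) & (sub["cm"] <= hi)]
            if members.empty:
                raise RuntimeError(
                    f"hotspot at {chrom}:{peak_cm:.1f} has no member MTA"
                )
            lmk, rmk = _flanking_markers(chrom_map, lo, hi)
            lbp = int(chrom_map.loc[lmk, "bp"])
            rbp = int(chrom_map.loc[rmk, "bp"])
            out.append(
                Hotspot(
                    id=f"QTL{chrom}.{ordinal}",
                    chromosome=chrom,
                    left_cm=lo,
                    peak_cm=peak_cm,
                    right_cm=hi,
                    member_mtas=members.reset_index(drop=True),
                    traits=set(members["trait"]),
                    years=set(members["environment"]),
                    left_marker=lmk,
                    right_marker=rmk,
                    left_bp=lbp,
                    right_bp=rbp,
                    ci_mb=physical_interval(lbp, rbp),
                    max_neglog10p=float(members["neglog10p"].max()),
                )
            )
    return out


def filter_hotspots(
    hs: list[Hotspot],
    centromeres: dict[str, float],
    max_ci_mb: float = 35.0,
    min_years: int = 2,
    min_traits: int = 2,
) -> tuple[list[Hotspot], pd.DataFrame]:
    """Apply the hotspot exclusion rules.

    Retained hotspots have the centromere outside [left_cm, right_cm], a
    physical CI <= ``max_ci_mb`` Mb, and member MTAs from at least
    ``min_years`` years and ``min_traits`` traits.  The second return value
    logs every dropped hotspot with its reasons.
    """
    kept: list[Hotspot] = []
    log_rows = []
    for h in hs:
        if h.chromosome not in centromeres:
            raise ValueError(f"no centromere position for chromosome {h.chromosome}")
        reasons = []
        cent = centromeres[h.chromosome]
        if h.left_cm <= cent <= h.right_cm:
            reasons.append("centromere")
        if h.ci_mb > max_ci_mb:
            reasons.append("ci_mb")
        years = {y for y in h.years if y != "mean"}
        if len(years) < min_years:
            reasons.append("years")
        if len(h.traits) < min_traits:
            reasons.append("traits")
        if reasons:
            log_rows.append((h.id, ";".join(reasons)))
        else:
            kept.append(h)
    return kept, pd.DataFrame(log_rows, columns=["hotspot", "reasons"])


def hotspot_table(hs: list[Hotspot]) -> pd.DataFrame:
    """Summary table, one row per hotspot (left-peak-right cM convention)."""
    return pd.DataFrame(
        {
            "hotspot": [h.id for h in hs],
            "chrom": [h.chromosome for h in hs],
            "position_cm": [
                f"{h.left_cm:.0f}-{h.peak_cm:.0f}-{h.right_cm:.0f}" for h in hs
            ],
            "n_mtas": [len(h.member_mtas) for h in hs],
            "max_neglog10p": [h.max_neglog10p for h in hs],
            "n_years": [len({y for y in h.years if y != "mean"}) for h in hs],
            "n_traits": [len(h.traits) for h in hs],
            "left_marker": [h.left_marker for h in hs],
            "left_bp": [h.left_bp for h in hs],
            "right_marker": [h.right_marker for h in hs],
            "right_bp": [h.right_bp for h in hs],
            "ci_mb": [h.ci_mb for h in hs],
            "traits": [",".join(sorted(h.traits)) for h in hs],
        }
    )


def reference_intervals() -> pd.DataFrame:
    """Published flanking-marker physical positions for eleven bread-wheat
    QTL hotspots, used as a regression fixture for the interval arithmetic.

    Columns: hotspot, chrom, left_marker, left_bp, right_marker, right_bp,
    ci_mb (the published interval length in Mb)."""
    from importlib.resources import files

    path = files("wheatgwas").joinpath("data/hotspot_flanks.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def hotspots_to_bed(hs: list[Hotspot], path) -> None:
    """Write hotspot physical intervals as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for h in hs:
            lo = min(h.left_bp, h.right_bp)
            hi = max(h.left_bp, h.right_bp)
            fh.write(f"{h.chromosome}\t{lo - 1}\t{hi}\t{h.id}\n")
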