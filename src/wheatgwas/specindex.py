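"""Spectral vegetation indices from four-band canopy reflectance.

The camera bands are green (550 nm), red (660 nm), red edge (735 nm) and
near infrared (790 nm).  Six indices are supported — five structural
(NDVI, RDVI, MSAVI, MTVI2, GNDVI) and one chlorophyll index (TCARI/OSAVI)
— plus leaf area index (LAI) predicted from MTVI2 through a linear
calibration against ceptometer ground truth.

The exact algebra of each index is frozen in :data:`VI_REGISTRY` so tests
can pin it; all indices are functions of reflectance only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PlotSpectra",
    "VIRecord",
    "VI_REGISTRY",
    "VI_NAMES",
    "compute_vi",
    "compute_vi_table",
    "LAIModel",
    "calibrate_lai",
    "VIComputationError",
]

STAGES = ("anthesis", "postanthesis")


class VIComputationError(ValueError):
    """Division by zero or negative radicand in an index formula."""


@dataclass(frozen=True)
class PlotSpectra:
    """Mean reflectance of one plot in the four camera bands, in [0, 1]."""

    plot_id: str
    stage: str
    green: float
    red: float
    rededge: float
    nir: float

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        for band in ("green", "red", "rededge", "nir"):
            v = getattr(self, band)
            if not math.isfinite(v):
                raise ValueError(f"{band} reflectance is not finite: {v}")


@dataclass(frozen=True)
class VIRecord:
    plot_id: str
    stage: str
    index_name: str
    value: float
    flagged: bool = False  # True when the formula was degenerate for this input


def _ndvi(g, r, re, nir):
    den = nir + r
    if den == 0:
        raise VIComputationError("NDVI: NIR + red is zero")
    return (nir - r) / den


def _rdvi(g, r, re, nir):
    den = nir + r
    if den <= 0:
        raise VIComputationError("RDVI: NIR + red must be positive")
    return (nir - r) / math.sqrt(den)


def _msavi(g, r, re, nir):
    rad = (2 * nir + 1) ** 2 - 8 * (nir - r)
    if rad < 0:
        raise VIComputationError("MSAVI: negative radicand")
    return (2 * nir + 1 - math.sqrt(rad)) / 2


def _mtvi2(g, r, re, nir):
    if r < 0:
        raise VIComputationError("MTVI2: negative red reflectance")
    rad = (2 * nir + 1) ** 2 - (6 * nir - 5 * math.sqrt(r)) - 0.5
    if rad < 0:
        raise VIComputationError("MTVI2: negative radicand")
    if rad == 0:
        raise VIComputationError("MTVI2: zero denominator")
    return 1.5 * (1.2 * (nir - g) - 2.5 * (r - g)) / math.sqrt(rad)


def _gndvi(g, r, re, nir):
    den = nir + g
    if den == 0:
        raise VIComputationError("GNDVI: NIR + green is zero")
    return (nir - g) / den


def _tcari_osavi(g, r, re, nir):
    if r == 0:
        raise VIComputationError("TCARI/OSAVI: red reflectance is zero")
    tcari = 3 * ((re - r) - 0.2 * (re - g) * (re / r))
    osavi_den = nir + r + 0.16
    if osavi_den == 0:
        raise VIComputationError("TCARI/OSAVI: OSAVI denominator is zero")
    osavi = (1 + 0.16) * (nir - r) / osavi_den
    if osavi == 0:
        raise VIComputationError("TCARI/OSAVI: OSAVI is zero")
    return tcari / osavi


#: index name -> callable(green, red, rededge, nir) -> value
VI_REGISTRY = {
    "NDVI": _ndvi,
    "RDVI": _rdvi,
    "MSAVI": _msavi,
    "MTVI2": _mtvi2,
    "GNDVI": _gndvi,
    "TCARI_OSAVI": _tcari_osavi,
}

VI_NAMES = tuple(VI_REGISTRY)


def compute_vi(s: PlotSpectra, index_name: str) -> VIRecord:
    """Compute one vegetation index for one plot.

    Degenerate inputs (zero denominators, negative radicands) yield a
    *flagged* record carrying NaN rather than a silent NaN.
    """
    if index_name not in VI_REGISTRY:
        raise KeyError(f"unknown index {index_name!r}; known: {sorted(VI_REGISTRY)}")
    try:
        value = VI_REGISTRY[index_name](s.green, s.red, s.rededge, s.nir)
        return VIRecord(s.plot_id, s.stage, index_name, float(value))
    except VIComputationError:
        return VIRecord(s.plot_id, s.stage, index_name, float("nan"), flagged=True)


def compute_vi_table(spectra: list[PlotSpectra], indices=VI_NAMES) -> pd.DataFrame:
    """Tidy table of all requested indices for all plots."""
    recs = [compute_vi(s, name) for s in spectra for name in indices]
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in recs],
            "stage": [r.stage for r in recs],
            "index_name": [r.index_name for r in recs],
            "value": [r.value for r in recs],
            "flagged": [r.flagged for r in recs],
        }
    )


@dataclass
class LAIModel:
    """Linear LAI ~ MTVI2 calibration: LAI = intercept + slope * MTVI2."""

    intercept: float
    slope: float
    r_squared: float
    slope_se: float
    n_calibration: int

    def predict(self, mtvi2) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(mtvi2, dtype=float)


def calibrate_lai(mtvi2_records, lai_measured) -> LAIModel:
    """Fit LAI = a + b * MTVI2 by ordinary least squares on calibration plots.

    Parameters
    ----------
    mtvi2_records : list of VIRecord (index_name == "MTVI2")
    lai_measured : list of (plot_id, LAI) from ceptometer ground truth.

    Requires at least two calibration plots with distinct MTVI2 values.
    """
    mtvi2_by_plot = {r.plot_id: r.value for r in mtvi2_records if r.index_name == "MTVI2"}
    pairs = [(mtvi2_by_plot[p], lai) for p, lai in lai_measured if p in mtvi2_by_plot]
    if len(pairs) < 2:
        raise ValueError("need >= 2 calibration plots with MTVI2 values")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: MTVI2 constant across plots")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return LAIModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        slope_se=float(fit.bse[1]),
        n_calibration=len(pairs),
    )
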