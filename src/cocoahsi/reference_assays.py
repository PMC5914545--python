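"""Arithmetic layer of the wet-lab reference methods.

Covers the fermentation-index absorbance ratio, ordinary least-squares
standard curves (ferulic acid for Folin-Ciocalteu total polyphenols, Trolox
for the ABTS/QUENCHER antioxidant assay), curve inversion with
calibration-range warnings, and replicate precision statistics (SE, CV).

The fermentation index is read at 460 and 530 nm on an acidified methanol
extract; anthocyanins absorbing near 500-550 nm degrade during fermentation,
so the A460/A530 ratio rises with fermentation degree, values above 1
indicating a well-fermented bean. (Part of the older literature quotes
520 nm for the denominator wavelength; 530 nm is used here.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayPrecision",
    "fermentation_index",
    "fit_standard_curve",
    "absorbance_to_concentration",
    "precision_stats",
]


@dataclass
class StandardCurve:
    """OLS line ``absorbance = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r2: float
    concentration_units: str
    absorbance_units: str = "AU"
    range_min: float = 0.0
    range_max: float = np.inf


@dataclass
class AssayPrecision:
    """Replicate precision: SE = SD/sqrt(n), CV = 100*SD/mean (percent)."""

    se: float
    cv: float
    n: int


def fermentation_index(a460: float, a530: float) -> tuple[float, str]:
    """FI = A460/A530; FI strictly above 1 is classed well_fermented
    (FI = 1 exactly counts as under_fermented)."""
    if a530 <= 0:
        raise ValueError(f"A530 must be > 0, got {a530}")
    if a460 < 0:
        raise ValueError(f"A460 must be >= 0, got {a460}")
    fi = a460 / a530
    return fi, ("well_fermented" if fi > 1 else "under_fermented")


def fit_standard_curve(concentrations, absorbances,
                       concentration_units: str = "") -> StandardCurve:
    """Fit an OLS standard curve through >= 3 (concentration, absorbance)
    points; stores the fitted calibration range."""
    conc = np.asarray(concentrations, dtype=float).ravel()
    ab = np.asarray(absorbances, dtype=float).ravel()
    if conc.size != ab.size or conc.size < 3:
        raise ValueError("need >= 3 paired points to fit a standard curve")
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations are equal; degenerate design")
    fit = stats.linregress(conc, ab)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        concentration_units=concentration_units,
        range_min=float(conc.min()),
        range_max=float(conc.max()),
    )


def absorbance_to_concentration(curve: StandardCurve, absorbance) -> np.ndarray | float:
    """Invert the standard curve: (A - intercept)/slope. Warns when the
    result lies outside the fitted calibration range."""
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    conc = (np.asarray(absorbance, dtype=float) - curve.intercept) / curve.slope
    out_of_range = (conc < curve.range_min) | (conc > curve.range_max)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.count_nonzero(out_of_range))} value(s) outside the "
            f"calibration range [{curve.range_min:g}, {curve.range_max:g}] "
            f"{curve.concentration_units}",
            stacklevel=2,
        )
    return float(conc) if conc.ndim == 0 else conc


def precision_stats(replicates) -> AssayPrecision:
    """SE and CV of a replicate series (sample SD, n-1 denominator)."""
    reps = np.asarray(replicates, dtype=float).ravel()
    if reps.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = reps.mean()
    sd = reps.std(ddof=1)
    if mean == 0 and sd > 0:
        raise ValueError("CV undefined for zero-mean replicates")
    cv = 0.0 if sd == 0 else 100.0 * sd / mean
    return AssayPrecision(se=float(sd / np.sqrt(reps.size)), cv=float(cv), n=reps.size)
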