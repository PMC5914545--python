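"""Spectral pretreatments: SNV, area normalisation, Savitzky-Golay
smoothing/derivatives, and ordered pretreatment pipelines.

All transforms are row-independent (one spectrum per row) and accept a 1-D
spectrum or a 2-D ``rows x bands`` matrix. SNV uses the sample SD (n-1
denominator); area normalisation is L1 (sum of absolute values), well defined
for derivative spectra; Savitzky-Golay derivatives are scaled by the physical
band spacing (per nm, per nm^2) and use mirror padding at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_filter

__all__ = [
    "PretreatmentSpec",
    "snv",
    "area_normalize",
    "savitzky_golay",
    "apply_pretreatment",
]

#: relative tolerance on wavelength-spacing uniformity
SPACING_RTOL = 1e-3


def _as_matrix(spectra) -> tuple[np.ndarray, bool]:
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim != 2:
        raise ValueError(f"spectra must be 1-D or 2-D, got {arr.ndim}-D")
    return arr, False


def snv(spectra) -> np.ndarray:
    """Standard Normal Variate: per spectrum, subtract the mean and divide by
    the sample SD. Removes per-spectrum additive offsets and multiplicative
    scatter factors."""
    X, squeeze = _as_matrix(spectra)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands per spectrum")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero((sd.ravel() == 0) | (np.ptp(X, axis=1) == 0))
    if flat.size:
        raise ValueError(f"constant spectrum (zero variance) in row(s) {flat.tolist()}")
    out = (X - mean) / sd
    return out[0] if squeeze else out


def area_normalize(spectra) -> np.ndarray:
    """Divide each spectrum by its L1 area, so sum(|x|) = 1 afterwards."""
    X, squeeze = _as_matrix(spectra)
    area = np.abs(X).sum(axis=1, keepdims=True)
    flat = np.flatnonzero(area.ravel() == 0)
    if flat.size:
        raise ValueError(f"all-zero spectrum in row(s) {flat.tolist()}")
    out = X / area
    return out[0] if squeeze else out


def _check_savgol(window: int, polyorder: int, deriv: int) -> None:
    if window % 2 != 1 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder (got window={window}, "
            f"polyorder={polyorder})"
        )
    if deriv < 0 or deriv > polyorder:
        raise ValueError(f"deriv must lie in [0, polyorder], got {deriv}")


def savitzky_golay(
    spectra,
    wavelengths: np.ndarray,
    window: int = 5,
    polyorder: int = 2,
    deriv: int = 0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative along the band axis.

    Fits a degree-``polyorder`` polynomial to each centered ``window`` by
    least squares and evaluates its ``deriv``-th derivative at the center,
    scaled by the band spacing in nm (so derivatives are per nm, per nm^2).
    The wavelength axis must be uniform to 0.1%; edges use mirror padding.
    """
    _check_savgol(window, polyorder, deriv)
    X, squeeze = _as_matrix(spectra)
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size != X.shape[1]:
        raise ValueError(
            f"wavelength axis ({wl.size}) does not match band count ({X.shape[1]})"
        )
    if X.shape[1] < window:
        raise ValueError(f"need at least window={window} bands, got {X.shape[1]}")
    spacing = np.diff(wl)
    h = spacing.mean()
    if np.any(np.abs(spacing - h) > SPACING_RTOL * abs(h)):
        raise ValueError(
            "wavelength axis is not uniform to 0.1%; resample the spectra "
            "onto a uniform grid before Savitzky-Golay filtering"
        )
    out = savgol_filter(X, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=h, axis=1, mode="mirror")
    return out[0] if squeeze else out


_STEP_NAMES = {"none", "area_normalisation", "snv", "savgol"}


@dataclass(frozen=True)
class PretreatmentSpec:
    """An ordered list of pretreatment steps.

    Each step is a dict with a ``name`` in {none, area_normalisation, snv,
    savgol}; savgol steps carry ``window``, ``polyorder`` and ``deriv``.
    The spec travels with fitted models so pixel-level prediction applies
    exactly the training pretreatment.
    """

    steps: tuple = field(default_factory=lambda: ({"name": "none"},))

    def __post_init__(self) -> None:
        steps = []
        for step in self.steps:
            if isinstance(step, str):
                step = {"name": step}
            step = dict(step)
            name = step.get("name")
            if name not in _STEP_NAMES:
                raise ValueError(f"unknown pretreatment step {name!r}")
            if name == "savgol":
                step.setdefault("window", 5)
                step.setdefault("polyorder", 2)
                step.setdefault("deriv", 0)
                _check_savgol(step["window"], step["polyorder"], step["deriv"])
            steps.append(step)
        if not steps:
            steps = [{"name": "none"}]
        object.__setattr__(self, "steps", tuple(tuple(sorted(s.items())) for s in steps))

    def as_dicts(self) -> list[dict]:
        return [dict(s) for s in self.steps]

    # -- constructors ------------------------------------------------------
    @classmethod
    def none(cls) -> "PretreatmentSpec":
        """log(1/R) absorbance as-is."""
        return cls(({"name": "none"},))

    @classmethod
    def snv(cls) -> "PretreatmentSpec":
        return cls(({"name": "snv"},))

    @classmethod
    def area(cls) -> "PretreatmentSpec":
        return cls(({"name": "area_normalisation"},))

    @classmethod
    def savgol_derivative(cls, deriv: int, window: int = 5, polyorder: int = 2) -> "PretreatmentSpec":
        """First/second derivative with 5-point, 2nd-order smoothing."""
        return cls(({"name": "savgol", "window": window,
                     "polyorder": polyorder, "deriv": deriv},))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"steps": self.as_dicts()}

    @classmethod
    def from_dict(cls, payload: dict) -> "PretreatmentSpec":
        return cls(tuple(payload["steps"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PretreatmentSpec":
        return cls.from_dict(yaml.safe_load(text))

    def describe(self) -> str:
        parts = []
        for step in self.as_dicts():
            if step["name"] == "savgol":
                parts.append(f"savgol({step['window']},{step['polyorder']},d{step['deriv']})")
            else:
                parts.append(step["name"])
        return " -> ".join(parts)


def apply_pretreatment(spectra, spec: PretreatmentSpec,
                       wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Apply the steps of ``spec`` in order. ``wavelengths`` is required when
    the spec contains a savgol step. All parameters are validated before any
    computation runs."""
    if not isinstance(spec, PretreatmentSpec):
        spec = PretreatmentSpec(tuple(spec))
    steps = spec.as_dicts()
    if any(s["name"] == "savgol" for s in steps) and wavelengths is None:
        raise ValueError("wavelengths are required for savgol pretreatment")
    out = np.asarray(spectra, dtype=float)
    for step in steps:
        name = step["name"]
        if name == "none":
            continue
        if name == "snv":
            out = snv(out)
        elif name == "area_normalisation":
            out = area_normalize(out)
        elif name == "savgol":
            out = savitzky_golay(out, wavelengths, window=step["window"],
                                 polyorder=step["polyorder"], deriv=step["deriv"])
    return out
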