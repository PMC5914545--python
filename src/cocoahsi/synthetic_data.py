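"""Synthetic single-bean reference panels and push-broom SWIR scenes.

Emulates the study design the downstream chemometrics assumes: 17 batches of
10 fermented cocoa beans, each bean imaged on two sides (340 mean spectra),
with bean-level fermentation index (FI, dimensionless A460/A530 ratio), total
polyphenols (TP, mg ferulic-acid-eq g^-1) and antioxidant activity (AA, mmol
Trolox-eq kg^-1) following the published descriptive statistics
(means 0.98 / 68.4 / 186.1, SDs 0.34 / 54.5 / 116.1) and pairwise Pearson
correlations r(TP,AA) = 0.876, r(FI,TP) = -0.570, r(FI,AA) = -0.443.

Scenes are rendered through a Beer-Lambert mixing model over a small library
of SWIR endmembers (phenolic, anthocyanin, lipid, water/carbonyl,
carbohydrate) on a 240-band 1000-2495 nm axis, then converted to 14-bit
detector counts with white/dark reference frames, per-pixel multiplicative
scatter gain, additive offset, Gaussian count noise and whole-column detector
defects — the artefacts the absorbance calibration, bad-pixel filter and
SNV-type pretreatments are designed to remove.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube_io import Hypercube, write_envi

__all__ = [
    "PanelParams",
    "EndmemberSet",
    "SceneGeometry",
    "SceneParams",
    "RawScene",
    "sample_reference_panel",
    "build_endmembers",
    "default_band_library",
    "default_wavelength_grid",
    "render_scene",
    "panel_to_csv",
    "panel_from_csv",
    "save_scene",
]

VARIABLES = ("FI", "TP", "AA")

#: published descriptive statistics of the calibration set (order FI, TP, AA)
TABLE_MEANS = (0.98, 68.4, 186.1)
TABLE_SDS = (0.34, 54.5, 116.1)
#: pairwise Pearson correlations, order FI, TP, AA
TABLE_CORR = (
    (1.0, -0.570, -0.443),
    (-0.570, 1.0, 0.876),
    (-0.443, 0.876, 1.0),
)

#: 240-band push-broom SWIR axis
N_BANDS = 240
WAVELENGTH_MIN = 1000.0
WAVELENGTH_MAX = 2495.0

#: 14-bit HgCdTe detector
DETECTOR_MAX = 2**14 - 1

_CALIBRATION_SEED = 0xC0C0A  # internal, independent of user seeds
_CALIBRATION_N = 60_000
_CALIBRATION_ITERS = 25


def default_wavelength_grid() -> np.ndarray:
    """The camera's 240-band wavelength axis, 1000-2495 nm."""
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, N_BANDS)


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelParams:
    """Bean-level trivariate (FI, TP, AA) distribution parameters.

    The panel is drawn from a zero-truncated multivariate normal with a
    batch-level mean shift carrying ``between_batch_fraction`` of the total
    variance. ``mean``/``sd``/``corr`` are the *target* post-truncation
    moments; the parent (pre-truncation) parameters are calibrated internally
    so the truncated draw reproduces them.
    """

    mean: tuple[float, float, float] = TABLE_MEANS
    sd: tuple[float, float, float] = TABLE_SDS
    corr: tuple[tuple[float, float, float], ...] = TABLE_CORR
    between_batch_fraction: float = 0.5
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (np.inf, np.inf, np.inf)

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if corr.shape != (3, 3):
            raise ValueError("correlation matrix must be 3x3 (order FI, TP, AA)")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() <= 0:
            raise ValueError(
                f"correlation matrix is not positive definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if np.any(sd <= 0):
            raise ValueError("all SDs must be > 0")
        if not (0.0 <= self.between_batch_fraction < 1.0):
            raise ValueError("between_batch_fraction must lie in [0, 1)")
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if np.any(lo > hi):
            raise ValueError("lower truncation bounds must not exceed upper bounds")

    def _key(self) -> tuple:
        return (
            self.mean, self.sd, tuple(map(tuple, np.asarray(self.corr))),
            self.between_batch_fraction, self.lower, self.upper,
        )


def _simulate_hierarchical(mu, sd, corr, frac, lower, upper, n_batches,
                           beans_per_batch, rng, max_rounds: int = 1000):
    """Hierarchical truncated-MVN draw; truncation by resampling (never
    clipping), preserving the correlation structure.

    Each bean is ``mu + batch_shift + residual``; out-of-bounds beans have
    their residual redrawn while keeping the batch shift. Beans deep in the
    tail of a pathological batch (no acceptance within 150 rounds) fall back
    to privately redrawing shift and residual together, which preserves the
    bean-level marginal at the cost of slightly weakening within-batch
    correlation in those rare batches. Returns (values, acceptance_rate).
    """
    cov = corr * np.outer(sd, sd)
    n = n_batches * beans_per_batch
    # degenerate (zero-width) truncation pins a variable at its bound
    pinned = lower == upper
    chol_b = np.linalg.cholesky(cov * frac) if frac > 0 else np.zeros((3, 3))
    chol_w = np.linalg.cholesky(cov * (1.0 - frac))
    shifts = rng.standard_normal((n_batches, 3)) @ chol_b.T
    shifts = np.repeat(shifts, beans_per_batch, axis=0)
    values = np.empty((n, 3))
    pending = np.ones(n, dtype=bool)
    n_draws = 0
    switch_round = 150
    for round_no in range(max_rounds):
        k = int(pending.sum())
        if k == 0:
            break
        if round_no >= switch_round and frac > 0:
            shifts[pending] = rng.standard_normal((k, 3)) @ chol_b.T
        resid = rng.standard_normal((k, 3)) @ chol_w.T
        cand = mu + shifts[pending] + resid
        cand[:, pinned] = lower[pinned]
        ok = np.all((cand >= lower) & (cand <= upper), axis=1)
        idx = np.flatnonzero(pending)
        values[idx[ok]] = cand[ok]
        pending[idx[ok]] = False
        n_draws += k
    else:
        raise RuntimeError(
            "truncation resampling did not converge; bounds are too tight "
            "for the requested moments"
        )
    return values, n / max(n_draws, 1)


_parent_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _univariate_parent(target_mean: float, target_sd: float,
                       lower: float, upper: float) -> tuple[float, float]:
    """Parent (m, s) of a univariate truncated normal whose truncated mean
    and SD match the targets (root solve on the closed-form moments)."""
    from scipy import optimize, stats as sps

    def residual(theta):
        m, log_s = theta
        s = np.exp(log_s)
        a, b = (lower - m) / s, (upper - m) / s
        mt, vt = sps.truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [mt - target_mean, np.sqrt(vt) - target_sd]

    sol = optimize.root(residual, x0=[target_mean, np.log(target_sd)],
                        method="hybr")
    if not sol.success:
        return target_mean, target_sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _calibrated_parent(params: PanelParams):
    """Parent (pre-truncation) MVN parameters whose zero-truncated draw
    reproduces the target moments. The univariate marginals are solved in
    closed form first; the joint (cross-truncation and batch-hierarchy)
    corrections follow by damped fixed-point iteration on simulated moments.
    Deterministic: internal fixed seed."""
    key = params._key()
    if key in _parent_cache:
        return _parent_cache[key]
    target_mu = np.asarray(params.mean, dtype=float)
    target_sd = np.asarray(params.sd, dtype=float)
    target_corr = np.asarray(params.corr, dtype=float)
    lower = np.asarray(params.lower, dtype=float)
    upper = np.asarray(params.upper, dtype=float)
    mu, sd, corr = target_mu.copy(), target_sd.copy(), target_corr.copy()
    pinned = lower == upper

    # skip calibration when truncation is (effectively) inactive
    with np.errstate(invalid="ignore"):
        z_lo = (target_mu - lower) / target_sd
        z_hi = (upper - target_mu) / target_sd
    if np.all(pinned | ((np.nan_to_num(z_lo, nan=np.inf) > 5) &
                        (np.nan_to_num(z_hi, nan=np.inf) > 5))):
        _parent_cache[key] = (mu, sd, corr)
        return mu, sd, corr

    for i in range(3):
        if not pinned[i] and (z_lo[i] < 5 or z_hi[i] < 5):
            mu[i], sd[i] = _univariate_parent(
                target_mu[i], target_sd[i], lower[i], upper[i])

    rng = np.random.default_rng(_CALIBRATION_SEED)
    beans_per_batch = 10
    free = ~pinned
    # stage 1: coarse fixed point; stage 2: refine with larger simulations
    # and average the settled iterates to beat simulation noise. The mean/SD
    # response to the parent parameters has derivative < 1 under deep
    # truncation, so those updates take a gain above 1.
    stages = ((30, _CALIBRATION_N, 1.2), (16, 4 * _CALIBRATION_N, 0.8))
    tail: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for n_iter, n_sim, damp in stages:
        n_batches = n_sim // beans_per_batch
        for it in range(n_iter):
            vals, _ = _simulate_hierarchical(
                mu, sd, corr, params.between_batch_fraction, lower, upper,
                n_batches, beans_per_batch, rng)
            m = vals.mean(axis=0)
            s = vals.std(axis=0, ddof=1)
            mu[free] += damp * (target_mu - m)[free]
            sd[free] *= (target_sd[free] / s[free]) ** min(damp, 0.8)
            if free.sum() > 1:
                # correlation update only over non-pinned variables (a
                # pinned variable has zero variance and no defined r)
                R = np.asarray(target_corr, dtype=float).copy()
                fi = np.flatnonzero(free)
                R[np.ix_(fi, fi)] = np.corrcoef(vals[:, fi], rowvar=False)
                corr = corr + min(damp, 0.5) * (target_corr - R)
                corr = np.clip((corr + corr.T) / 2.0, -0.999, 0.999)
                np.fill_diagonal(corr, 1.0)
                # repair positive definiteness if the update overshoots
                w, V = np.linalg.eigh(corr)
                if w.min() <= 1e-8:
                    w = np.clip(w, 1e-8, None)
                    corr = V @ np.diag(w) @ V.T
                    d = np.sqrt(np.diag(corr))
                    corr = corr / np.outer(d, d)
            if n_sim > _CALIBRATION_N and it >= n_iter - 8:
                tail.append((mu.copy(), sd.copy(), corr.copy()))
    if tail:
        mu = np.mean([t[0] for t in tail], axis=0)
        sd = np.mean([t[1] for t in tail], axis=0)
        corr = np.mean([t[2] for t in tail], axis=0)
        np.fill_diagonal(corr, 1.0)
    _parent_cache[key] = (mu, sd, corr)
    return mu, sd, corr


def sample_reference_panel(
    n_batches: int,
    beans_per_batch: int,
    params: PanelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a bean-level reference panel.

    Returns a DataFrame with columns ``batch_id, bean_id, FI, TP, AA`` (ids
    1-based), one row per bean, with ``attrs['acceptance_rate']`` recording
    the truncation resampling acceptance rate.
    """
    params = params or PanelParams()
    if n_batches < 1 or beans_per_batch < 1:
        raise ValueError("n_batches and beans_per_batch must be >= 1")
    mu, sd, corr = _calibrated_parent(params)
    rng = np.random.default_rng(seed)
    values, acc = _simulate_hierarchical(
        mu, sd, corr, params.between_batch_fraction,
        np.asarray(params.lower, dtype=float), np.asarray(params.upper, dtype=float),
        n_batches, beans_per_batch, rng)
    panel = pd.DataFrame(
        {
            "batch_id": np.repeat(np.arange(1, n_batches + 1), beans_per_batch),
            "bean_id": np.tile(np.arange(1, beans_per_batch + 1), n_batches),
            "FI": values[:, 0],
            "TP": values[:, 1],
            "AA": values[:, 2],
        }
    )
    panel.attrs["acceptance_rate"] = acc
    return panel


def panel_to_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=["batch_id", "bean_id", "FI", "TP", "AA"])


def panel_from_csv(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = {"batch_id", "bean_id", "FI", "TP", "AA"} - set(panel.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return panel


# ---------------------------------------------------------------------------
# Endmembers
# ---------------------------------------------------------------------------

@dataclass
class EndmemberSet:
    """Absorptivity spectra (absorbance per unit concentration) sharing one
    wavelength axis."""

    wavelengths: np.ndarray
    spectra: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name, spec in self.spectra.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != self.wavelengths.shape:
                raise ValueError(f"endmember {name!r} does not match the wavelength axis")
            if np.any(spec < 0):
                raise ValueError(f"endmember {name!r} has negative absorptivity")
            self.spectra[name] = spec


def default_band_library() -> dict[str, list[tuple[float, float, float]]]:
    """Bell-shaped SWIR band assignments (center nm, width nm, amplitude).

    Lipid bands at 1724/1743 and 2307/2326 nm (C-H stretch first overtone and
    combination bands of the high cocoa-butter fraction), water/carbonyl at
    1919 nm, carbohydrate C-H overtones at 1208 and 1340 nm, phenolic O-H
    near 1420 and 1660 nm, anthocyanin near 1440 nm.
    """
    return {
        "phenolic": [(1420.0, 12.0, 1.0), (1660.0, 16.0, 0.7)],
        "anthocyanin": [(1440.0, 12.0, 1.0)],
        "lipid": [(1724.0, 8.0, 1.0), (1743.0, 8.0, 0.9),
                  (2307.0, 8.0, 0.8), (2326.0, 8.0, 0.7)],
        "water_carbonyl": [(1919.0, 25.0, 1.0)],
        "carbohydrate": [(1208.0, 14.0, 0.8), (1340.0, 16.0, 1.0)],
    }


def build_endmembers(
    wavelengths: np.ndarray,
    band_specs: dict[str, list[tuple[float, float, float]]] | None = None,
) -> EndmemberSet:
    """Evaluate a band library into endmember spectra on ``wavelengths``.

    Each component is a sum of Gaussian bands; a band whose center falls
    outside the grid is skipped with a warning.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    band_specs = band_specs if band_specs is not None else default_band_library()
    spectra: dict[str, np.ndarray] = {}
    for name, bands in band_specs.items():
        spec = np.zeros_like(wl)
        for center, width, amplitude in bands:
            if not (wl[0] <= center <= wl[-1]):
                warnings.warn(
                    f"band center {center} nm outside grid "
                    f"[{wl[0]:.0f}, {wl[-1]:.0f}] nm; skipped ({name})",
                    stacklevel=2,
                )
                continue
            spec = spec + amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)
        spectra[name] = spec
    return EndmemberSet(wavelengths=wl, spectra=spectra)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneGeometry:
    """Frame and bean-layout geometry.

    The camera images a 35 mm field of view onto 320 detector pixels
    (0.109 mm/pixel). Default frames are cropped to the bean tray region.
    Beans are axis-aligned ellipses placed on a rows x cols grid, emulating
    ten seeds at a time on the scanning stage.
    """

    n_lines: int = 64
    n_samples: int = 160
    field_of_view_mm: float = 35.0
    detector_pixels: int = 320
    rows: int = 2
    cols: int = 5
    semi_line: float = 11.0    # ellipse semi-axis along lines, px
    semi_sample: float = 12.0  # ellipse semi-axis along samples, px

    @property
    def pixel_size_mm(self) -> float:
        return self.field_of_view_mm / self.detector_pixels

    @property
    def n_beans(self) -> int:
        return self.rows * self.cols

    def centers(self) -> np.ndarray:
        """Bean centroid grid, row-major, as (line, sample) pairs."""
        lines = (np.arange(self.rows) + 0.5) * self.n_lines / self.rows
        samples = (np.arange(self.cols) + 0.5) * self.n_samples / self.cols
        return np.array([(l, s) for l in lines for s in samples])


@dataclass(frozen=True)
class SceneParams:
    """Radiometric and noise configuration of a rendered scene.

    The default configuration is the study condition: 14-bit counts with
    Gaussian read/shot noise, ~5% per-pixel multiplicative scatter gain, a
    small additive count offset, a few whole-column detector defects, per-bean
    compositional jitter of the bulk components, and a per-(bean, side)
    chemistry-coupling error between the surface seen by the camera and the
    ground whole-bean reference assay. :meth:`noiseless` switches every
    stochastic term off for oracle tests.
    """

    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    white_level: float = 12000.0
    dark_level: float = 400.0
    count_noise_sd: float = 30.0
    gain_sd: float = 0.05
    offset_sd: float = 20.0
    n_dead_columns: int = 2
    n_hot_columns: int = 1
    jitter_sd: float = 0.05
    tp_coupling_sd: float = 30.0  # mg/g, surface-vs-bulk assay mismatch
    fi_coupling_sd: float = 0.50  # dimensionless
    background_absorbance: float = 0.05
    within_bean_gradient: float = 0.0

    @classmethod
    def noiseless(cls, **overrides) -> "SceneParams":
        """All stochastic terms off: exact forward/inverse round trips."""
        base = dict(
            count_noise_sd=0.0, gain_sd=0.0, offset_sd=0.0,
            n_dead_columns=0, n_hot_columns=0,
            tp_coupling_sd=0.0, fi_coupling_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RawScene:
    """A rendered push-broom acquisition plus its ground truth.

    ``raw`` holds detector counts (lines x samples x bands); ``white``/``dark``
    are reference frames (samples x bands). ``labels`` is the true label map
    (0 = background, beans numbered 1..K row-major), ``true_spectra`` the
    noiseless per-bean mean absorbance (K x bands), and ``bean_table`` the
    per-bean identities, reference values and mixing concentrations.
    """

    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    true_spectra: np.ndarray
    bean_table: pd.DataFrame
    params: SceneParams
    seed: int
    bad_pixels: list[tuple[int, int, str]] = field(default_factory=list)


# default mixing scales: concentration per unit endmember amplitude
_C_PHEN_SCALE = 0.30   # at mean TP (68.4 mg/g)
_C_ANTH_SCALE = 0.05
_C_LIPID = 0.45
_C_WATER = 0.50
_C_CARB = 0.35


def _bean_concentrations(panel: pd.DataFrame, params: SceneParams,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Per-bean mixing concentrations from the reference values.

    Phenolic concentration is proportional to TP (plus coupling error);
    anthocyanin decreases strictly and nonlinearly with FI, mirroring pigment
    degradation over fermentation; lipid, water/carbonyl and carbohydrate are
    constant bulk components with per-bean jitter. AA has no endmember of its
    own — it is only reachable through its correlation with TP.
    """
    n = len(panel)
    tp_eff = panel["TP"].to_numpy() + rng.normal(0.0, params.tp_coupling_sd, n) \
        if params.tp_coupling_sd > 0 else panel["TP"].to_numpy().copy()
    fi_eff = panel["FI"].to_numpy() + rng.normal(0.0, params.fi_coupling_sd, n) \
        if params.fi_coupling_sd > 0 else panel["FI"].to_numpy().copy()
    jitter = (rng.normal(0.0, params.jitter_sd, (n, 3))
              if params.jitter_sd > 0 else np.zeros((n, 3)))
    conc = pd.DataFrame(
        {
            "phenolic": np.clip(_C_PHEN_SCALE * tp_eff / TABLE_MEANS[1], 0.0, None),
            "anthocyanin": _C_ANTH_SCALE * np.exp(-(fi_eff - TABLE_MEANS[0]) / TABLE_SDS[0]),
            "lipid": _C_LIPID * (1.0 + jitter[:, 0]),
            "water_carbonyl": _C_WATER * (1.0 + jitter[:, 1]),
            "carbohydrate": _C_CARB * (1.0 + jitter[:, 2]),
        }
    )
    return conc


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth broadband absorbance baseline of the bean matrix."""
    return 0.55 + 0.10 * (wl - WAVELENGTH_MIN) / (WAVELENGTH_MAX - WAVELENGTH_MIN)


def _label_map(geometry: SceneGeometry) -> np.ndarray:
    centers = geometry.centers()
    a, b = geometry.semi_line, geometry.semi_sample
    # ellipses must fit in the frame without overlap
    for cl, cs in centers:
        if cl - a < 0 or cl + a > geometry.n_lines or cs - b < 0 or cs + b > geometry.n_samples:
            raise ValueError(
                f"bean ellipse at (line {cl:.1f}, sample {cs:.1f}) does not fit "
                f"inside the {geometry.n_lines}x{geometry.n_samples} frame"
            )
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dl = abs(centers[i][0] - centers[j][0])
            ds = abs(centers[i][1] - centers[j][1])
            if (dl / (2 * a)) ** 2 + (ds / (2 * b)) ** 2 < 1.0:
                raise ValueError(
                    f"bean ellipses {i + 1} and {j + 1} overlap; adjust geometry"
                )
    ll, ss = np.mgrid[0:geometry.n_lines, 0:geometry.n_samples]
    labels = np.zeros((geometry.n_lines, geometry.n_samples), dtype=np.int32)
    for k, (cl, cs) in enumerate(centers, start=1):
        inside = ((ll - cl) / a) ** 2 + ((ss - cs) / b) ** 2 <= 1.0
        labels[inside] = k
    return labels


def render_scene(
    panel: pd.DataFrame,
    endmembers: EndmemberSet,
    params: SceneParams | None = None,
    seed: int = 0,
) -> RawScene:
    """Render one push-broom acquisition of the beans in ``panel``.

    ``panel`` supplies one row per bean (at most ``geometry.n_beans``); beans
    fill the layout grid row-major. Per-pixel absorbance follows Beer-Lambert
    mixing ``A = baseline + sum_k c_k E_k``; raw counts are
    ``dark + gain * (white - dark) * 10^(-A) + offset + noise`` clipped to the
    14-bit detector range, with configured dead/hot detector columns applied
    last. Deterministic given ``seed``.
    """
    params = params or SceneParams()
    if len(panel) == 0:
        raise ValueError("panel must contain at least one bean")
    geometry = params.geometry
    if len(panel) > geometry.n_beans:
        raise ValueError(
            f"panel has {len(panel)} beans but the layout holds {geometry.n_beans}"
        )
    if len(panel) < geometry.n_beans:
        geometry = replace(
            geometry,
            rows=1 if len(panel) <= geometry.cols else geometry.rows,
            cols=min(len(panel), geometry.cols),
        )
        if geometry.n_beans != len(panel):
            raise ValueError(
                f"cannot lay out {len(panel)} beans on a {geometry.rows}x{geometry.cols} grid"
            )
    wl = endmembers.wavelengths
    rng = np.random.default_rng(seed)
    labels = _label_map(geometry)
    conc = _bean_concentrations(panel.reset_index(drop=True), params, rng)

    # noiseless per-bean absorbance spectra (K x bands)
    base = _baseline(wl)
    true_spectra = np.tile(base, (len(panel), 1))
    for name, spec in endmembers.spectra.items():
        if name in conc.columns:
            true_spectra += np.outer(conc[name].to_numpy(), spec)

    n_lines, n_samples, n_bands = geometry.n_lines, geometry.n_samples, wl.size
    absorbance = np.full((n_lines, n_samples, n_bands), params.background_absorbance)
    for k in range(1, len(panel) + 1):
        mask = labels == k
        absorbance[mask] = true_spectra[k - 1]
    if params.within_bean_gradient > 0:
        # optional smooth spatial modulation of the total bean absorbance
        ll = np.arange(n_lines)[:, None] / max(n_lines - 1, 1)
        mod = 1.0 + params.within_bean_gradient * (ll - 0.5) * 2.0
        absorbance[labels > 0] *= np.broadcast_to(
            mod[:, :, None], absorbance.shape)[labels > 0]

    # reference frames: smooth band-dependent illumination profile
    profile = 1.0 - 0.3 * ((wl - 1700.0) / (WAVELENGTH_MAX - WAVELENGTH_MIN)) ** 2
    white = np.tile(params.dark_level + (params.white_level - params.dark_level) * profile,
                    (n_samples, 1))
    dark = np.full((n_samples, n_bands), params.dark_level)

    gain = (np.exp(rng.normal(0.0, params.gain_sd, (n_lines, n_samples)))
            if params.gain_sd > 0 else np.ones((n_lines, n_samples)))
    offset = (rng.normal(0.0, params.offset_sd, (n_lines, n_samples))
              if params.offset_sd > 0 else np.zeros((n_lines, n_samples)))
    raw = dark[None, :, :] + gain[:, :, None] * (white - dark)[None, :, :] \
        * np.power(10.0, -absorbance) + offset[:, :, None]
    if params.count_noise_sd > 0:
        raw = raw + rng.normal(0.0, params.count_noise_sd, raw.shape)
    raw = np.clip(raw, 0.0, DETECTOR_MAX)

    bad_pixels: list[tuple[int, int, str]] = []
    n_bad = params.n_dead_columns + params.n_hot_columns
    if n_bad > 0:
        flat = rng.choice(n_samples * n_bands, size=n_bad, replace=False)
        for i, f in enumerate(flat):
            s, b = divmod(int(f), n_bands)
            kind = "dead" if i < params.n_dead_columns else "hot"
            raw[:, s, b] = 0.0 if kind == "dead" else DETECTOR_MAX
            bad_pixels.append((s, b, kind))

    bean_table = panel.reset_index(drop=True).copy()
    bean_table.insert(0, "label", np.arange(1, len(panel) + 1))
    for col in conc.columns:
        bean_table[f"c_{col}"] = conc[col].to_numpy()

    return RawScene(
        raw=raw, white=white, dark=dark, wavelengths=wl.copy(),
        labels=labels, true_spectra=true_spectra, bean_table=bean_table,
        params=params, seed=seed, bad_pixels=bad_pixels,
    )


def save_scene(scene: RawScene, directory, stem: str = "scene") -> dict:
    """Write a scene as an ENVI raw/white/dark triplet + PNG label map +
    JSON manifest. Returns the manifest dict."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    triplet = {}
    for name, arr in (("raw", scene.raw),
                      ("white", scene.white[None, :, :]),
                      ("dark", scene.dark[None, :, :])):
        cube = Hypercube(np.asarray(arr, dtype=np.float32), scene.wavelengths)
        hdr = directory / f"{stem}_{name}.hdr"
        dat = directory / f"{stem}_{name}.raw"
        write_envi(cube, hdr, dat, interleave="bil")
        triplet[name] = {"header": hdr.name, "data": dat.name}
    label_path = directory / f"{stem}_labels.png"
    Image.fromarray(scene.labels.astype(np.uint8), mode="P").save(label_path)
    manifest = {
        "convention": "(line, sample) = (row, column), 0-based",
        "files": triplet,
        "labels": label_path.name,
        "seed": scene.seed,
        "bad_pixels": [list(bp) for bp in scene.bad_pixels],
        "beans": scene.bean_table.to_dict(orient="records"),
        "true_spectra": scene.true_spectra.tolist(),
        "wavelengths_nm": scene.wavelengths.tolist(),
    }
    (directory / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
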