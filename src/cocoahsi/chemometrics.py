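"""PLS1 calibration, batch-paired splitting, cross-validation and metrics.

The calibration core is NIPALS PLS1 on mean-centered (unscaled) spectra:
at each component the weight vector is ``w = X'y / ||X'y||``, scores
``t = Xw``, loadings ``p = X't / t't``, ``q = y't / t't``, with X and y
deflated after every component. The regression vector in original units is
``b = W (P'W)^{-1} q`` with intercept ``y_mean - x_mean·b``, so prediction is
a single affine map. Model selection follows the published procedure: full
(leave-one-bean-out) cross-validation on the calibration set, RMSECV as a
function of the number of latent variables (LVs), global minimum selected
with ties broken toward fewer LVs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import PretreatmentSpec

__all__ = [
    "SplitAssignment",
    "PLSModel",
    "CVCurve",
    "ModelMetrics",
    "split_by_batch",
    "fit_pls",
    "predict",
    "cross_validate",
    "select_lv",
    "evaluate",
    "rpd",
    "pearson",
    "r2_explained_variance",
    "coefficient_peaks",
]


# ---------------------------------------------------------------------------
# Batch-paired splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Per-bean calibration/validation roles; both sides of a bean share its
    role. ``table`` has columns (batch_id, bean_id, role)."""

    table: pd.DataFrame
    seed: int
    fraction: float

    def role_of(self, batch_id, bean_id) -> str:
        match = self.table[(self.table.batch_id == batch_id)
                           & (self.table.bean_id == bean_id)]
        if match.empty:
            raise KeyError(f"bean (batch {batch_id}, bean {bean_id}) not in split")
        return match.role.iloc[0]

    def roles_for(self, ids: pd.DataFrame) -> np.ndarray:
        """Vectorised role lookup for an identity frame with batch_id/bean_id
        columns (e.g. a SpectraTable's ids — sides inherit the bean role)."""
        merged = ids.merge(self.table, on=["batch_id", "bean_id"], how="left")
        if merged.role.isna().any():
            missing = ids[merged.role.isna()][["batch_id", "bean_id"]]
            raise KeyError(f"beans missing from split: {missing.values.tolist()[:5]}")
        return merged.role.to_numpy()


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_by_batch(panel: pd.DataFrame, fraction: float = 0.7,
                   seed: int = 0) -> SplitAssignment:
    """Batch-paired random split: within each batch, round(fraction * n)
    beans (half-up) become calibration, the rest validation. With 17 batches
    of 10 beans and fraction 0.7 this yields 7/3 per batch, i.e. 238
    calibration and 102 validation spectra after two-sided scanning."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    records = []
    for batch_id, group in panel.groupby("batch_id", sort=True):
        beans = group["bean_id"].to_numpy()
        if beans.size < 2:
            raise ValueError(f"batch {batch_id} has fewer than 2 beans")
        n_cal = _round_half_up(fraction * beans.size)
        n_cal = min(max(n_cal, 1), beans.size - 1)  # both roles non-empty
        chosen = rng.choice(beans, size=n_cal, replace=False)
        chosen_set = set(chosen.tolist())
        for bean in beans:
            records.append({
                "batch_id": batch_id,
                "bean_id": bean,
                "role": "calibration" if bean in chosen_set else "validation",
            })
    return SplitAssignment(table=pd.DataFrame(records), seed=seed, fraction=fraction)


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted PLS1 calibration.

    Prediction in original y units is ``X @ b + intercept``; the stored
    weights ``W``, X-loadings ``P`` and y-loadings ``q`` reproduce the same
    prediction through the NIPALS recursion. The attached pretreatment spec
    travels with the model so pixel-level application repeats the training
    pretreatment exactly.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # bands x n_lv
    x_loadings: np.ndarray  # bands x n_lv
    y_loadings: np.ndarray  # n_lv
    b: np.ndarray
    intercept: float
    n_lv: int
    pretreatment: PretreatmentSpec = field(default_factory=PretreatmentSpec.none)
    wavelengths: np.ndarray | None = None
    constituent: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.b + self.intercept

    def predict_via_scores(self, X: np.ndarray) -> np.ndarray:
        """Prediction through the W/P/q recursion (deflation replayed);
        used to verify the closed-form b."""
        Xd = np.asarray(X, dtype=float) - self.x_mean
        y = np.full(Xd.shape[0], float(self.y_mean))
        for a in range(self.n_lv):
            t = Xd @ self.weights[:, a]
            y += t * self.y_loadings[a]
            Xd -= np.outer(t, self.x_loadings[:, a])
        return y

    # -- serialisation: structured text (JSON) model file ------------------
    def to_json(self, path=None) -> str:
        payload = {
            "constituent": self.constituent,
            "n_lv": int(self.n_lv),
            "pretreatment": self.pretreatment.to_dict(),
            "wavelengths_nm": None if self.wavelengths is None
            else np.asarray(self.wavelengths).tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "b": self.b.tolist(),
            "intercept": float(self.intercept),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            x_mean=np.array(payload["x_mean"]),
            y_mean=payload["y_mean"],
            weights=np.array(payload["weights"]),
            x_loadings=np.array(payload["x_loadings"]),
            y_loadings=np.array(payload["y_loadings"]),
            b=np.array(payload["b"]),
            intercept=payload["intercept"],
            n_lv=payload["n_lv"],
            pretreatment=PretreatmentSpec.from_dict(payload["pretreatment"]),
            wavelengths=None if payload["wavelengths_nm"] is None
            else np.array(payload["wavelengths_nm"]),
            constituent=payload.get("constituent", ""),
        )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int, strict: bool = True):
    """NIPALS PLS1 on centered data. Returns (W, P, q, b_per_lv) where
    b_per_lv[a] is the regression vector using a+1 components.

    When the covariance X'y vanishes before ``n_lv`` components (rank
    exhausted), strict mode raises naming the achievable rank; non-strict
    mode stops extracting and carries the last regression vector forward
    (further components cannot change the fit, so the CV curve goes flat).
    """
    n, p = Xc.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    Xd = Xc.copy()
    yd = yc.copy()
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc) + 1e-300
    achieved = n_lv
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        tt = 0.0
        if nw > 1e-12 * scale:
            w = w / nw
            t = Xd @ w
            tt = t @ t
        if nw <= 1e-12 * scale or tt <= 0:
            if strict:
                raise np.linalg.LinAlgError(
                    f"X'y vanished at component {a + 1}; achievable rank is {a}"
                )
            achieved = a
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = yd @ t / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd -= q[a] * t
    # b for every truncation level
    b_per_lv = []
    for a in range(1, achieved + 1):
        R = np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
        b_per_lv.append(W[:, :a] @ R)
    if achieved == 0:
        b_per_lv.append(np.zeros(p))  # y uncorrelated with X: predict the mean
    while len(b_per_lv) < n_lv:
        b_per_lv.append(b_per_lv[-1])
    return W[:, :achieved], P[:, :achieved], q[:achieved], b_per_lv


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    pretreatment: PretreatmentSpec | None = None,
    wavelengths: np.ndarray | None = None,
    constituent: str = "",
) -> PLSModel:
    """Fit a NIPALS PLS1 model on (already pretreated) spectra.

    Mean-centers X and y, runs ``n_lv`` NIPALS components with deflation and
    assembles the regression vector so that ``predict`` works directly in
    original y units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"X rows ({X.shape[0]}) must equal len(y) ({y.size})")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if y.size <= n_lv:
        raise ValueError(f"need more than n_lv={n_lv} samples, got {y.size}")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to calibrate")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_lv > rank:
        raise ValueError(
            f"n_lv={n_lv} exceeds the rank of the centered spectra matrix "
            f"(achievable rank {rank})"
        )
    W, P, q, b_per_lv = _nipals_pls1(Xc, yc, n_lv)
    b = b_per_lv[-1]
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q,
        b=b, intercept=y_mean - x_mean @ b, n_lv=n_lv,
        pretreatment=pretreatment or PretreatmentSpec.none(),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
        constituent=constituent,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict in original y units for already-pretreated spectra."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Cross-validation and LV selection
# ---------------------------------------------------------------------------

@dataclass
class CVCurve:
    """RMSECV per LV count 1..max_lv."""

    rmsecv: np.ndarray
    grouping: str = "leave-one-bean-out"

    def __post_init__(self) -> None:
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        if self.rmsecv.size == 0:
            raise ValueError("CV curve is empty")
        if not np.all(np.isfinite(self.rmsecv)) or np.any(self.rmsecv < 0):
            raise ValueError("RMSECV values must be finite and non-negative")

    @property
    def lv_range(self) -> np.ndarray:
        return np.arange(1, self.rmsecv.size + 1)


def cross_validate(X: np.ndarray, y: np.ndarray, groups, max_lv: int) -> CVCurve:
    """Full leave-one-group-out cross-validation.

    One group is one bean (its two sides leave together, preventing leakage
    between a bean's two spectra); singleton groups give classical
    leave-one-out. For every held-out group and every LV count 1..max_lv the
    model is refit on the remaining rows and the group predicted; RMSECV
    aggregates all held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if groups.shape[0] != y.size or X.shape[0] != y.size:
        raise ValueError("X, y and groups must align row-wise")
    unique = pd.unique(groups)
    if unique.size < 2:
        raise ValueError("a single group contains all rows; cannot cross-validate")
    sq_err = np.zeros(max_lv)
    for g in unique:
        held = groups == g
        X_tr, y_tr = X[~held], y[~held]
        x_mean = X_tr.mean(axis=0)
        y_mean = y_tr.mean()
        _, _, _, b_per_lv = _nipals_pls1(X_tr - x_mean, y_tr - y_mean, max_lv,
                                         strict=False)
        Xh = X[held] - x_mean
        for a, b in enumerate(b_per_lv):
            pred = Xh @ b + y_mean
            sq_err[a] += np.sum((pred - y[held]) ** 2)
    return CVCurve(rmsecv=np.sqrt(sq_err / y.size))


def select_lv(curve: CVCurve) -> int:
    """LV count at the global RMSECV minimum; ties break toward fewer LVs."""
    return int(np.argmin(curve.rmsecv)) + 1


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ModelMetrics:
    """Regression performance on one evaluated set.

    ``r2`` is the squared Pearson correlation of reference and prediction
    (the convention of the chemometric software the procedure mirrors);
    ``slope`` comes from regressing predictions on references; ``bias`` is
    the mean prediction error; ``rpd`` = SD of the reference values of the
    evaluated set / RMSE, when requested.
    """

    r2: float
    rmse: float
    slope: float
    bias: float
    rpd: float | None
    n: int


def rpd(sd_ref: float, rmse: float) -> float:
    """Ratio of performance to deviation: SD of the evaluated set's
    reference values over the RMSE on that set."""
    if rmse <= 0:
        raise ValueError("RPD is undefined for zero RMSE")
    return sd_ref / rmse


def evaluate(y_ref, y_pred, sd_ref: float | None = None) -> ModelMetrics:
    """Compute R^2 (squared Pearson r), RMSE, slope, bias and (optionally)
    RPD for one evaluated set. ``sd_ref`` must be the SD of the reference
    values of *this* set (calibration SD for RPD_cv, validation SD for
    RPD_p); omit it to skip the RPD. Zero RMSE with an RPD requested is an
    error (RPD undefined for perfect predictions)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size or y_ref.size < 2:
        raise ValueError("y_ref and y_pred must have equal length >= 2")
    if np.ptp(y_ref) == 0:
        raise ValueError("reference values have zero variance")
    r = np.corrcoef(y_ref, y_pred)[0, 1]
    rmse = float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))
    slope = float(np.polyfit(y_ref, y_pred, 1)[0])
    bias = float(np.mean(y_pred - y_ref))
    rpd_value = None if sd_ref is None else rpd(sd_ref, rmse)
    return ModelMetrics(r2=float(r * r), rmse=rmse, slope=slope, bias=bias,
                        rpd=rpd_value, n=y_ref.size)


def r2_explained_variance(y_ref, y_pred) -> float:
    """1 - SSE/SST: the explained-variance flavour of R^2, exposed under a
    distinct name to avoid confusion with the squared-correlation ``r2``."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    sst = np.sum((y_ref - y_ref.mean()) ** 2)
    if sst == 0:
        raise ValueError("reference values have zero variance")
    return float(1.0 - np.sum((y_ref - y_pred) ** 2) / sst)


def pearson(x, y):
    """Pearson correlation with a two-sided p-value (t transform, n-2 df)
    and a significance flag: 'highly_significant' (P < 0.01),
    'significant' (P < 0.05) or 'ns'."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs equal-length vectors with n >= 3")
    r, p = stats.pearsonr(x, y)
    flag = "highly_significant" if p < 0.01 else ("significant" if p < 0.05 else "ns")
    return float(r), float(p), flag


# ---------------------------------------------------------------------------
# Regression-coefficient peaks
# ---------------------------------------------------------------------------

def coefficient_peaks(model: PLSModel, n_peaks: int = 5) -> list[float]:
    """Wavelengths of the largest |b| local extrema, descending by magnitude.

    Mirrors the practice of reading the most influential wavelengths off a
    PLS regression-coefficient plot. Returns fewer than ``n_peaks`` (with a
    warning) when the coefficient vector has fewer extrema.
    """
    if model.wavelengths is None:
        raise ValueError("model has no wavelength axis")
    mag = np.abs(model.b)
    if not np.any(mag > 0):
        warnings.warn("regression coefficient vector is identically zero", stacklevel=2)
        return []
    n = mag.size
    is_peak = np.zeros(n, dtype=bool)
    if n == 1:
        is_peak[0] = True
    else:
        interior = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:]) \
            & ((mag[1:-1] > mag[:-2]) | (mag[1:-1] > mag[2:]))
        is_peak[1:-1] = interior
        is_peak[0] = mag[0] > mag[1]
        is_peak[-1] = mag[-1] > mag[-2]
    idx = np.flatnonzero(is_peak & (mag > 0))
    order = idx[np.argsort(mag[idx])[::-1]]
    if order.size < n_peaks:
        warnings.warn(
            f"requested {n_peaks} peaks but only {order.size} extrema exist",
            stacklevel=2,
        )
    chosen = order[:n_peaks]
    return [float(model.wavelengths[i]) for i in chosen]
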