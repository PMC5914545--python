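"""Pixel-level application of a calibration and per-bean summaries.

A fitted PLS model is applied to every bean pixel's spectrum — pretreated
with the exact spec the model was trained with — producing a chemical image
of the constituent; background stays masked. Per-bean values are unweighted
means of the pixel predictions (for non-linear pretreatments such as SNV
this differs from predicting the bean's mean spectrum; the summary always
averages pixel predictions). Predictions are not clipped to the calibration
range; out-of-range pixels are counted in the image metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .chemometrics import PLSModel
from .hypercube_io import Hypercube
from .preprocessing import apply_pretreatment
from .segmentation import LabelMap

__all__ = ["ChemicalImage", "predict_map", "bean_level_summary", "render_map"]


@dataclass
class ChemicalImage:
    """Per-pixel predicted constituent map; NaN where label == 0."""

    values: np.ndarray
    constituent: str
    units: str
    model_id: str = ""
    display_range: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return bool(np.all(np.isnan(self.values)))


def _label_image(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)


def predict_map(
    model: PLSModel,
    cube: Hypercube,
    labels,
    units: str = "",
    calibration_range: tuple[float, float] | None = None,
) -> ChemicalImage:
    """Apply ``model`` at single-pixel level over the bean pixels of ``cube``.

    Each bean pixel's spectrum is pretreated with the model's attached spec
    and pushed through the regression vector; background pixels stay NaN.
    The cube's wavelength axis must match the model's.
    """
    if model.wavelengths is not None and (
        model.wavelengths.size != cube.wavelengths.size
        or not np.allclose(model.wavelengths, cube.wavelengths)
    ):
        raise ValueError(
            "wavelength axis mismatch between model and cube:\n"
            f"  model: {np.asarray(model.wavelengths).round(2).tolist()[:5]}... "
            f"({np.asarray(model.wavelengths).size} bands)\n"
            f"  cube:  {cube.wavelengths.round(2).tolist()[:5]}... "
            f"({cube.wavelengths.size} bands)"
        )
    label_img = _label_image(labels)
    if label_img.shape != cube.data.shape[:2]:
        raise ValueError("label map does not match cube spatial dimensions")
    values = np.full(label_img.shape, np.nan)
    mask = label_img > 0
    if not mask.any():
        warnings.warn("label map has no bean pixels; returning an empty map",
                      stacklevel=2)
        return ChemicalImage(values=values, constituent=model.constituent,
                             units=units, metadata={"n_pixels": 0})
    pixels = cube.data[mask]  # n_pixels x bands
    treated = apply_pretreatment(pixels, model.pretreatment, cube.wavelengths)
    pred = model.predict(treated)
    values[mask] = pred
    metadata = {"n_pixels": int(mask.sum()), "pretreatment": model.pretreatment.describe()}
    if calibration_range is not None:
        lo, hi = calibration_range
        metadata["n_out_of_range"] = int(np.count_nonzero((pred < lo) | (pred > hi)))
        metadata["calibration_range"] = [float(lo), float(hi)]
    return ChemicalImage(
        values=values,
        constituent=model.constituent,
        units=units,
        model_id=f"pls-{model.constituent}-{model.n_lv}lv",
        display_range=(float(np.nanmin(values)), float(np.nanmax(values))),
        metadata=metadata,
    )


def bean_level_summary(
    image: ChemicalImage,
    labels,
    panel: pd.DataFrame | None = None,
    label_to_row: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Unweighted mean of the pixel predictions per bean, joined to the
    reference values.

    ``panel`` holds the per-bean reference values with a column named after
    the image's constituent; ``label_to_row`` maps labels to panel row
    positions (default: label k -> row k-1).
    """
    label_img = _label_image(labels)
    if label_img.shape != image.values.shape:
        raise ValueError("label map does not match image dimensions")
    records = []
    for k in np.unique(label_img[label_img > 0]):
        mean_pred = float(np.nanmean(image.values[label_img == k]))
        rec = {"label": int(k), "predicted_mean": mean_pred}
        if panel is not None:
            row = label_to_row.get(int(k), int(k) - 1) if label_to_row else int(k) - 1
            if not (0 <= row < len(panel)):
                raise ValueError(f"label {k} has no matching panel row")
            ref = float(panel.iloc[row][image.constituent])
            rec["reference"] = ref
            rec["residual"] = mean_pred - ref
        records.append(rec)
    return pd.DataFrame(records)


def render_map(
    image: ChemicalImage,
    path,
    colormap: str = "viridis",
    annotations: bool = True,
    labels=None,
    references: pd.DataFrame | None = None,
) -> None:
    """Write the chemical image as a raster with a colorbar.

    With ``annotations`` and a label map, each bean is annotated with its
    predicted mean (white) and, when ``references`` (output of
    :func:`bean_level_summary`) is given, the reference value (black).
    """
    if not np.all(np.isfinite(image.values[~np.isnan(image.values)])):
        raise ValueError("chemical image contains non-finite predictions")
    fig, ax = plt.subplots(figsize=(7, 3.5))
    masked = np.ma.masked_invalid(image.values)
    im = ax.imshow(masked, cmap=colormap, interpolation="nearest")
    title = image.constituent or "prediction"
    if image.units:
        title += f" [{image.units}]"
    ax.set_title(title)
    ax.set_xlabel("sample")
    ax.set_ylabel("line")
    fig.colorbar(im, ax=ax, shrink=0.85)
    if annotations and labels is not None and not image.empty:
        label_img = _label_image(labels)
        summary = references if references is not None \
            else bean_level_summary(image, label_img)
        for _, row in summary.iterrows():
            k = int(row["label"])
            ys, xs = np.nonzero(label_img == k)
            cy, cx = ys.mean(), xs.mean()
            ax.text(cx, cy, f"{row['predicted_mean']:.3g}", color="white",
                    ha="center", va="center", fontsize=7)
            if "reference" in row and np.isfinite(row.get("reference", np.nan)):
                ax.text(cx, cy + 5, f"{row['reference']:.3g}", color="black",
                        ha="center", va="center", fontsize=7)
    try:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    finally:
        plt.close(fig)
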