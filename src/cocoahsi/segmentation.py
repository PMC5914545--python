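"""Bean/background segmentation and per-object mean spectrum extraction.

Beans absorb strongly against the scanning stage, so a global Otsu threshold
on the band-mean absorbance image separates them; a fixed threshold can be
supplied for regression tests. Objects are 8-connected, hole-filled, filtered
by a minimum area and ordered row-major by centroid (ascending centroid line,
then centroid sample). Coordinates follow (line, sample) = (row, column),
0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .hypercube_io import Hypercube

__all__ = ["LabelMap", "SpectraTable", "segment_beans", "extract_mean_spectra"]

#: default minimum object area in pixels at 0.109 mm/px
DEFAULT_MIN_AREA = 50


@dataclass
class LabelMap:
    """Integer label image (0 = background) plus an object table with
    columns (label, area, centroid_line, centroid_sample, bbox_*)."""

    labels: np.ndarray
    objects: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.labels.astype(np.uint8), mode="P").save(path)

    def objects_to_json(self, path) -> None:
        payload = {
            "convention": "(line, sample) = (row, column), 0-based",
            "objects": self.objects.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SpectraTable:
    """Per-object mean spectra with identity keys.

    ``ids`` has columns (batch_id, bean_id, side); ``spectra`` is the
    aligned (n_rows x bands) matrix on ``wavelengths``.
    """

    ids: pd.DataFrame
    spectra: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape != (len(self.ids), self.wavelengths.size):
            raise ValueError(
                f"spectra shape {self.spectra.shape} does not match "
                f"{len(self.ids)} rows x {self.wavelengths.size} bands"
            )
        key = self.ids[["batch_id", "bean_id", "side"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (batch, bean, side) keys: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        """Identity columns plus one column per wavelength (header = nm)."""
        frame = self.ids.copy()
        for j, wl in enumerate(self.wavelengths):
            frame[f"{wl:.4f}"] = self.spectra[:, j]
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        frame = pd.read_csv(path)
        id_cols = ["batch_id", "bean_id", "side"]
        missing = set(id_cols) - set(frame.columns)
        if missing:
            raise ValueError(f"spectra CSV missing identity columns: {sorted(missing)}")
        wl_cols = [c for c in frame.columns if c not in id_cols]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(
            ids=frame[id_cols].reset_index(drop=True),
            spectra=frame[wl_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
        )

    def concat(self, other: "SpectraTable") -> "SpectraTable":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("cannot concatenate tables on different wavelength axes")
        return SpectraTable(
            ids=pd.concat([self.ids, other.ids], ignore_index=True),
            spectra=np.vstack([self.spectra, other.spectra]),
            wavelengths=self.wavelengths,
        )


def segment_beans(
    cube: Hypercube,
    min_area: int = DEFAULT_MIN_AREA,
    threshold: float | None = None,
) -> LabelMap:
    """Segment beans from the background of a cleaned, cropped cube.

    The band-mean absorbance image is thresholded (Otsu unless ``threshold``
    is given; beans are the high-absorbance side), holes are filled, objects
    below ``min_area`` pixels are dropped, and the survivors are labelled
    with 8-connectivity and renumbered 1..K row-major by centroid.
    """
    mean_image = cube.data.mean(axis=2)
    if threshold is None:
        threshold = float(filters.threshold_otsu(mean_image))
    mask = mean_image > threshold
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    keep = [p for p in props if p.area >= min_area]
    if not keep:
        raise ValueError(
            f"no objects of at least {min_area} px found "
            f"(threshold used: {threshold:.4f})"
        )
    keep.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    relabeled = np.zeros_like(labels, dtype=np.int32)
    records = []
    for new_label, p in enumerate(keep, start=1):
        relabeled[labels == p.label] = new_label
        records.append(
            {
                "label": new_label,
                "area": int(p.area),
                "centroid_line": float(p.centroid[0]),
                "centroid_sample": float(p.centroid[1]),
                "bbox_min_line": int(p.bbox[0]),
                "bbox_min_sample": int(p.bbox[1]),
                "bbox_max_line": int(p.bbox[2]),
                "bbox_max_sample": int(p.bbox[3]),
            }
        )
    objects = pd.DataFrame(records)
    objects.attrs["threshold"] = threshold
    return LabelMap(labels=relabeled, objects=objects)


def extract_mean_spectra(
    cube: Hypercube,
    labels: LabelMap | np.ndarray,
    identity: dict[int, tuple] ,
) -> SpectraTable:
    """Unweighted per-object mean spectrum at each band.

    ``identity`` maps each label to (batch_id, bean_id, side); every label
    present in the map must be covered or an error is raised.
    """
    label_img = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    if label_img.shape != cube.data.shape[:2]:
        raise ValueError(
            f"label map shape {label_img.shape} does not match cube spatial "
            f"dimensions {cube.data.shape[:2]}"
        )
    present = np.unique(label_img)
    present = present[present > 0]
    missing = [int(k) for k in present if int(k) not in identity]
    if missing:
        raise ValueError(f"identity map missing labels: {missing}")
    rows = []
    spectra = np.empty((present.size, cube.bands))
    for i, k in enumerate(present):
        mask = label_img == k
        spectra[i] = cube.data[mask].mean(axis=0)
        batch_id, bean_id, side = identity[int(k)]
        rows.append({"batch_id": batch_id, "bean_id": bean_id, "side": side})
    return SpectraTable(
        ids=pd.DataFrame(rows),
        spectra=spectra,
        wavelengths=cube.wavelengths,
    )
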