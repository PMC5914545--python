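"""ENVI hypercube I/O and push-broom radiometric conversion.

Coordinate convention: (line, sample) = (row, column), 0-based everywhere.
A hypercube is stored in memory as ``lines x samples x bands`` regardless of
the on-disk interleave. White/dark reference frames are per detector element,
``samples x bands``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Hypercube",
    "BadPixelReport",
    "read_envi",
    "write_envi",
    "compute_absorbance",
    "remove_bad_pixels",
    "crop_bands",
]

# Reflectance clamp bounds: the floor prevents infinite absorbance from dead
# (zeroed) detector elements, the ceiling admits slightly >1 reflectance from
# noise on bright pixels. A clamped pixel is counted in the cube metadata.
REFLECTANCE_FLOOR = 1e-4
REFLECTANCE_CEIL = 1.5

#: absorbance value produced by the reflectance floor, -log10(1e-4)
ABSORBANCE_AT_FLOOR = -np.log10(REFLECTANCE_FLOOR)
#: absorbance value produced by the reflectance ceiling, -log10(1.5)
ABSORBANCE_AT_CEIL = -np.log10(REFLECTANCE_CEIL)

# ENVI data type codes <-> numpy dtypes (the subset this dialect supports)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """Absorbance (or count) hypercube: ``data[line, sample, band]``."""

    data: np.ndarray
    wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"hypercube data must be 3-D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all hypercube dimensions must be >= 1, got {self.data.shape}")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class BadPixelReport:
    """Log of detector elements modified by :func:`remove_bad_pixels`.

    ``table`` has columns (sample, band, reason) with
    reason in {"dead", "hot", "spike"}; ``n_replaced`` counts individual
    (line, sample, band) values that were overwritten.
    """

    table: pd.DataFrame
    n_replaced: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


# ---------------------------------------------------------------------------
# ENVI header + binary reader/writer
# ---------------------------------------------------------------------------

def _format_header(cube: Hypercube, interleave: str) -> str:
    code = _DTYPE_CODES[np.dtype(cube.data.dtype)]
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    return (
        "ENVI\n"
        "description = {cocoahsi hypercube; (line, sample) = (row, column), 0-based}\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        "wavelength = {" + wl + "}\n"
    )


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    # join brace-delimited multi-line values
    text = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def write_envi(cube: Hypercube, header_path, data_path, interleave: str = "bil") -> None:
    """Write a hypercube as an ENVI header + flat binary pair (little-endian)."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}; expected bil, bip or bsq")
    if np.dtype(cube.data.dtype) not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {cube.data.dtype} for ENVI output")
    # in-memory layout is (lines, samples, bands) == BIP band-fastest
    if interleave == "bip":
        arr = cube.data
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)  # lines, bands, samples
    else:  # bsq
        arr = cube.data.transpose(2, 0, 1)  # bands, lines, samples
    Path(header_path).write_text(_format_header(cube, interleave))
    arr_le = np.ascontiguousarray(arr).astype(arr.dtype.newbyteorder("<"), copy=False)
    Path(data_path).write_bytes(arr_le.tobytes())


def read_envi(header_path, data_path) -> Hypercube:
    """Read an ENVI header/binary pair into a ``lines x samples x bands`` cube."""
    fields = _parse_header(Path(header_path).read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from None
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}; expected bil, bip or bsq")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    byte_order = int(fields.get("byte order", "0"))
    wl_field = fields.get("wavelength", "")
    if not (wl_field.startswith("{") and wl_field.endswith("}")):
        raise ValueError("ENVI header missing wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in wl_field[1:-1].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    flat = np.frombuffer(Path(data_path).read_bytes(), dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise ValueError(
            f"data file holds {flat.size} values, header implies {expected}"
        )
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    data = np.ascontiguousarray(data).astype(data.dtype.newbyteorder("="), copy=False)
    return Hypercube(data=data, wavelengths=wavelengths, metadata={"interleave": interleave})


# ---------------------------------------------------------------------------
# Reflectance -> absorbance
# ---------------------------------------------------------------------------

def compute_absorbance(raw, white: np.ndarray, dark: np.ndarray,
                       wavelengths: np.ndarray | None = None) -> Hypercube:
    """Convert raw counts to absorbance with white/dark referencing.

    Reflectance ``R = (raw - dark) / (white - dark)`` is clamped to
    ``[1e-4, 1.5]`` and converted to absorbance ``A = -log10(R)``. The dark
    subtraction doubles as the per-image baseline correction.

    Parameters
    ----------
    raw
        Count hypercube (``Hypercube`` or ``lines x samples x bands`` array).
    white, dark
        Reference frames, ``samples x bands``; ``white`` must exceed ``dark``
        at every detector element.
    """
    if isinstance(raw, Hypercube):
        counts = np.asarray(raw.data, dtype=float)
        wavelengths = raw.wavelengths if wavelengths is None else wavelengths
    else:
        counts = np.asarray(raw, dtype=float)
        if wavelengths is None:
            raise ValueError("wavelengths required when raw is a bare array")
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.shape != (counts.shape[1], counts.shape[2]) or white.shape != dark.shape:
        raise ValueError(
            f"white/dark frames must be samples x bands = "
            f"{(counts.shape[1], counts.shape[2])}, got {white.shape} / {dark.shape}"
        )
    bad = white <= dark
    if np.any(bad):
        idx = np.argwhere(bad)
        head = ", ".join(f"(sample {s}, band {b})" for s, b in idx[:10])
        raise ValueError(
            f"white <= dark at {idx.shape[0]} detector element(s): {head}"
        )
    refl = (counts - dark[None, :, :]) / (white - dark)[None, :, :]
    n_clamped = int(np.count_nonzero((refl < REFLECTANCE_FLOOR) | (refl > REFLECTANCE_CEIL)))
    refl = np.clip(refl, REFLECTANCE_FLOOR, REFLECTANCE_CEIL)
    absorbance = -np.log10(refl)
    return Hypercube(
        data=absorbance,
        wavelengths=np.asarray(wavelengths, dtype=float),
        metadata={"n_clamped_pixels": n_clamped, "units": "absorbance"},
    )


# ---------------------------------------------------------------------------
# Bad pixel removal
# ---------------------------------------------------------------------------

def _neighbor_median(data: np.ndarray, s: int, b: int, bad_mask: np.ndarray) -> np.ndarray:
    """Median over valid 4-neighbors in the (sample, band) detector plane,
    per line. Returns a length-`lines` vector."""
    _, n_samples, n_bands = data.shape
    neighbors = []
    for ds, db in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ss, bb = s + ds, b + db
        if 0 <= ss < n_samples and 0 <= bb < n_bands and not bad_mask[ss, bb]:
            neighbors.append(data[:, ss, bb])
    if not neighbors:
        raise ValueError(
            f"detector element (sample {s}, band {b}) has no valid neighbors"
        )
    return np.median(np.stack(neighbors, axis=1), axis=1)


def remove_bad_pixels(
    cube: Hypercube,
    saturation_fraction: float = 0.5,
    spike_z: float = 6.0,
    min_spike_height: float = 0.5,
    max_bad_fraction: float = 0.2,
) -> tuple[Hypercube, BadPixelReport]:
    """Detect and repair defective detector elements in an absorbance cube.

    Push-broom defects live at fixed (sample, band) detector elements and
    affect every scanned line:

    * **dead** columns — zeroed counts clamp to the reflectance floor, giving
      a constant absorbance at the clamp value (zero variance along lines);
    * **hot** columns — saturated counts exceed the white reference
      (negative absorbance) in more than ``saturation_fraction`` of lines;
    * **spike** — an isolated spectral outlier: a single-band local extremum
      whose first differences on both sides exceed ``spike_z`` robust SDs
      and ``min_spike_height`` absorbance units (the absolute floor keeps
      smooth absorption-band curvature from triggering on low-noise scenes).

    Each flagged value is replaced by the median of its valid 4-neighbors in
    the (sample, band) plane. Applying the filter twice yields an empty
    second report.
    """
    if cube.lines < 3 or cube.samples < 3:
        raise ValueError("bad-pixel removal needs a cube of at least 3 lines x 3 samples")
    data = np.array(cube.data, dtype=float)
    n_lines, n_samples, n_bands = data.shape

    at_floor = data >= ABSORBANCE_AT_FLOOR - 1e-9
    # saturated counts exceed the white reference: reflectance > 1, A < 0
    saturated = data < 0.0
    ptp = data.max(axis=0) - data.min(axis=0)  # samples x bands
    dead_cols = (ptp == 0) & at_floor.all(axis=0)
    hot_cols = saturated.mean(axis=0) > saturation_fraction
    hot_cols &= ~dead_cols

    column_bad = dead_cols | hot_cols
    n_bad = int(column_bad.sum())
    if n_bad > max_bad_fraction * n_samples * n_bands:
        raise ValueError(
            f"{n_bad} of {n_samples * n_bands} detector elements are defective "
            f"(> {max_bad_fraction:.0%}); scene unusable"
        )

    records: list[tuple[int, int, str]] = []
    n_replaced = 0
    for s, b in np.argwhere(column_bad):
        data[:, s, b] = _neighbor_median(data, s, b, column_bad)
        records.append((int(s), int(b), "dead" if dead_cols[s, b] else "hot"))
        n_replaced += n_lines

    # Spectral spikes: per-pixel first differences along the band axis.
    if n_bands >= 3:
        diffs = np.diff(data, axis=2)
        threshold = max(spike_z * 1.4826 * np.median(np.abs(diffs)), min_spike_height)
        left = data[:, :, 1:-1] - data[:, :, :-2]
        right = data[:, :, 1:-1] - data[:, :, 2:]
        # local extremum: deviates in the same direction from both neighbors
        spikes = (left * right > 0) & (np.minimum(np.abs(left), np.abs(right)) > threshold)
        spike_idx = np.argwhere(spikes)
        seen: set[tuple[int, int]] = set()
        for l, s, bm in spike_idx:
            b = bm + 1
            lo, hi = max(b - 2, 0), min(b + 3, n_bands)
            window = np.delete(data[l, s, lo:hi], b - lo)
            data[l, s, b] = np.median(window)
            n_replaced += 1
            if (int(s), int(b)) not in seen:
                seen.add((int(s), int(b)))
                records.append((int(s), int(b), "spike"))

    table = pd.DataFrame(records, columns=["sample", "band", "reason"])
    cleaned = Hypercube(data=data, wavelengths=cube.wavelengths,
                        metadata=dict(cube.metadata))
    return cleaned, BadPixelReport(table=table, n_replaced=n_replaced)


# ---------------------------------------------------------------------------
# Band cropping
# ---------------------------------------------------------------------------

def crop_bands(cube: Hypercube, min_wavelength: float = 990.0) -> Hypercube:
    """Drop bands below ``min_wavelength`` (default 990 nm, below which the
    HgCdTe detector carries no useful signal)."""
    keep = cube.wavelengths >= min_wavelength
    if not keep.any():
        raise ValueError(
            f"min_wavelength {min_wavelength} nm removes all bands "
            f"(axis spans {cube.wavelengths[0]:.1f}-{cube.wavelengths[-1]:.1f} nm)"
        )
    if keep.all():
        return cube
    return Hypercube(
        data=cube.data[:, :, keep],
        wavelengths=cube.wavelengths[keep],
        metadata=dict(cube.metadata),
    )
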