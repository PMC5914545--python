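"""End-to-end study drivers: simulate a two-sided bean scan campaign, process
every scene to mean spectra, and run a pretreatment + PLS calibration with
batch-paired splitting and leave-one-bean-out cross-validation.

These helpers chain the public operations of the other modules exactly as a
user would: render raw frames -> absorbance -> bad-pixel removal -> band crop
-> segmentation -> mean spectra -> pretreatment -> PLS with RMSECV latent-
variable selection -> calibration/validation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .hypercube_io import compute_absorbance, crop_bands, remove_bad_pixels
from .preprocessing import PretreatmentSpec, apply_pretreatment
from .segmentation import SpectraTable, extract_mean_spectra, segment_beans
from .synthetic_data import (
    EndmemberSet,
    PanelParams,
    RawScene,
    SceneParams,
    build_endmembers,
    default_wavelength_grid,
    render_scene,
    sample_reference_panel,
)

__all__ = [
    "CalibrationResult",
    "process_scene",
    "simulate_dataset",
    "calibration_study",
    "metrics_table",
]

SIDES = ("A", "B")


def process_scene(
    scene: RawScene,
    batch_id: int,
    side: str,
    min_wavelength: float = 990.0,
    min_area: int = 50,
) -> SpectraTable:
    """Raw frames of one scene -> per-bean mean spectra.

    Segmentation must recover exactly the beans the scene was rendered with;
    segmented objects are matched to beans by their shared row-major order.
    """
    cube = compute_absorbance(scene.raw, scene.white, scene.dark,
                              wavelengths=scene.wavelengths)
    cube, _ = remove_bad_pixels(cube)
    cube = crop_bands(cube, min_wavelength)
    labels = segment_beans(cube, min_area=min_area)
    n_expected = len(scene.bean_table)
    if labels.n_objects != n_expected:
        raise ValueError(
            f"segmentation found {labels.n_objects} objects but the scene "
            f"holds {n_expected} beans (batch {batch_id}, side {side})"
        )
    identity = {
        k: (batch_id, int(scene.bean_table.bean_id.iloc[k - 1]), side)
        for k in range(1, n_expected + 1)
    }
    return extract_mean_spectra(cube, labels, identity)


def simulate_dataset(
    n_batches: int = 17,
    beans_per_batch: int = 10,
    panel_params: PanelParams | None = None,
    scene_params: SceneParams | None = None,
    endmembers: EndmemberSet | None = None,
    seed: int = 0,
    panel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SpectraTable]:
    """Simulate the full campaign: a reference panel and one scene per
    (batch, side), processed to a mean-spectra table (2 rows per bean).

    The two sides of a bean share its chemistry but are independent
    acquisitions (separate noise, scatter and surface-coupling draws).
    """
    scene_params = scene_params or SceneParams()
    if endmembers is None:
        endmembers = build_endmembers(default_wavelength_grid())
    if panel is None:
        panel = sample_reference_panel(n_batches, beans_per_batch,
                                       panel_params, seed=seed)
    master = np.random.default_rng(seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=(n_batches, len(SIDES)))
    table: SpectraTable | None = None
    truths = []
    for bi, (batch_id, group) in enumerate(panel.groupby("batch_id", sort=True)):
        for si, side in enumerate(SIDES):
            scene = render_scene(group, endmembers, scene_params,
                                 seed=int(scene_seeds[bi, si]))
            part = process_scene(scene, batch_id=int(batch_id), side=side)
            table = part if table is None else table.concat(part)
            truths.append(scene.true_spectra)
    # generator ground truth, row-aligned with the table (synthetic studies)
    table.true_spectra = np.vstack(truths)
    return panel, table


@dataclass
class CalibrationResult:
    """One pretreatment + PLS calibration with its selected LV count and the
    calibration / cross-validation / external-validation metric suite."""

    constituent: str
    pretreatment: PretreatmentSpec
    model: chem.PLSModel
    curve: chem.CVCurve
    n_lv: int
    calibration: chem.ModelMetrics
    rmsecv: float
    rpd_cv: float
    validation: chem.ModelMetrics
    split: chem.SplitAssignment


def _reference_vector(ids: pd.DataFrame, panel: pd.DataFrame,
                      constituent: str) -> np.ndarray:
    merged = ids.merge(panel[["batch_id", "bean_id", constituent]],
                       on=["batch_id", "bean_id"], how="left", validate="m:1")
    if merged[constituent].isna().any():
        raise ValueError("spectra table contains beans absent from the panel")
    return merged[constituent].to_numpy(dtype=float)


def calibration_study(
    table: SpectraTable,
    panel: pd.DataFrame,
    constituent: str,
    pretreatment: PretreatmentSpec | None = None,
    max_lv: int = 10,
    fraction: float = 0.7,
    split_seed: int = 0,
    split: chem.SplitAssignment | None = None,
) -> CalibrationResult:
    """Run the full published modelling procedure for one constituent.

    Batch-paired 70/30 bean split (both sides follow the bean), pretreatment,
    leave-one-bean-out RMSECV curve on the calibration set, LV count at the
    curve minimum, final model on the calibration set, external validation
    on the held-out beans. RPDs use the SD of the evaluated subset's own
    reference values.
    """
    pretreatment = pretreatment or PretreatmentSpec.none()
    if split is None:
        split = chem.split_by_batch(panel, fraction=fraction, seed=split_seed)
    roles = split.roles_for(table.ids)
    X = apply_pretreatment(table.spectra, pretreatment, table.wavelengths)
    y = _reference_vector(table.ids, panel, constituent)
    groups = (table.ids.batch_id.astype(str) + "_"
              + table.ids.bean_id.astype(str)).to_numpy()
    cal = roles == "calibration"
    val = roles == "validation"
    curve = chem.cross_validate(X[cal], y[cal], groups[cal], max_lv=max_lv)
    n_lv = chem.select_lv(curve)
    model = chem.fit_pls(X[cal], y[cal], n_lv, pretreatment=pretreatment,
                         wavelengths=table.wavelengths, constituent=constituent)
    sd_cal = float(np.std(y[cal], ddof=1))
    sd_val = float(np.std(y[val], ddof=1))
    calibration = chem.evaluate(y[cal], model.predict(X[cal]), sd_ref=sd_cal)
    validation = chem.evaluate(y[val], model.predict(X[val]), sd_ref=sd_val)
    rmsecv = float(curve.rmsecv[n_lv - 1])
    return CalibrationResult(
        constituent=constituent,
        pretreatment=pretreatment,
        model=model,
        curve=curve,
        n_lv=n_lv,
        calibration=calibration,
        rmsecv=rmsecv,
        rpd_cv=chem.rpd(sd_cal, rmsecv),
        validation=validation,
        split=split,
    )


def metrics_table(results: list[CalibrationResult]) -> pd.DataFrame:
    """Summary table mirroring the usual model-performance layout:
    LV, R2c, RMSEC, RMSECV, RPDcv, R2p, RMSEP, RPDp, slope, bias."""
    rows = []
    for res in results:
        rows.append({
            "constituent": res.constituent,
            "pretreatment": res.pretreatment.describe(),
            "LV": res.n_lv,
            "R2c": res.calibration.r2,
            "RMSEC": res.calibration.rmse,
            "RMSECV": res.rmsecv,
            "RPDcv": res.rpd_cv,
            "R2p": res.validation.r2,
            "RMSEP": res.validation.rmse,
            "RPDp": res.validation.rpd,
            "slope": res.validation.slope,
            "bias": res.validation.bias,
        })
    return pd.DataFrame(rows)
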