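# cocoahsi

Single-bean SWIR hyperspectral imaging chemometrics for cocoa.

Cocoa quality is routinely characterised by three wet-lab measurements —
fermentation index (FI, the A460/A530 absorbance ratio of an acidified
methanol extract; > 1 means well fermented), total polyphenols (TP, Folin–
Ciocalteu, mg ferulic-acid equivalent g⁻¹) and antioxidant activity (AA,
ABTS/QUENCHER, mmol Trolox equivalent kg⁻¹). All three are slow, destructive
and run on ground bulk samples. Push-broom NIR hyperspectral imaging
(1000–2495 nm, 240 bands) can instead record a full SWIR spectrum for every
pixel of every individual bean, and a PLS calibration against the wet-lab
references turns those spectra into per-bean — even per-pixel —
non-destructive predictions.

`cocoahsi` implements that whole workflow for researchers in food-quality
NIR chemometrics:

* **`synthetic_data`** — a forward model of the study: reference panels of
  17 batches × 10 beans drawn from a zero-truncated trivariate normal with
  the published moments (means 0.98 / 68.4 / 186.1, SDs 0.34 / 54.5 / 116.1,
  r(TP,AA) = 0.876, r(FI,TP) = −0.570, r(FI,AA) = −0.443) and raw
  push-broom scenes (raw/white/dark count frames, Beer–Lambert band mixing,
  scatter, noise, detector defects, ground-truth label maps).
* **`hypercube_io`** — ENVI header/binary I/O (BIL/BIP/BSQ), reflectance →
  absorbance with white/dark referencing, bad-pixel repair, band cropping.
* **`segmentation`** — Otsu bean/background separation, connected-component
  labelling, per-bean mean spectra (two sides per bean → 340 spectra).
* **`preprocessing`** — SNV, L1 area normalisation, Savitzky–Golay
  smoothing/derivatives (5 points, 2nd order), composable pretreatment specs
  that travel with fitted models.
* **`chemometrics`** — batch-paired 70/30 bean splits (238/102 spectra),
  NIPALS PLS1, full leave-one-bean-out cross-validation with RMSECV
  latent-variable selection, and the metric suite R², RMSEC/RMSECV/RMSEP,
  slope, bias, RPD = SD/RMSE, Pearson correlations with significance flags,
  regression-coefficient peak wavelengths.
* **`reference_assays`** — the arithmetic of the wet-lab methods: FI ratio
  and classification, OLS standard curves and inversion, SE/CV precision.
* **`chemical_imaging`** — pixel-level application of a calibration and
  per-bean summaries, rendered as annotated chemical maps.

The core calibration model is PLS1 on mean-centred spectra **X** against one
constituent **y**: NIPALS extracts latent variables
t = Xw (w ∝ X'y), deflates, and assembles b = W(P'W)⁻¹q so that
ŷ = Xb + b₀. Model complexity (the LV count) is chosen at the minimum of
the leave-one-bean-out RMSECV curve, and performance is reported as
R² (squared Pearson correlation), RMSE and RPD = SD_ref/RMSE on an external
batch-paired validation set.

## Worked example

Simulate the full campaign (17 batches × 10 beans × 2 sides, default noise),
then build SNV + PLS calibrations for all three constituents:

```python
import cocoahsi as chs
from cocoahsi.preprocessing import PretreatmentSpec
from cocoahsi.synthetic_data import SceneParams

panel, table = chs.simulate_dataset(17, 10, scene_params=SceneParams(), seed=0)
results = [
    chs.calibration_study(table, panel, const, PretreatmentSpec.snv(),
                          max_lv=10, split_seed=0)
    for const in ("FI", "TP", "AA")
]
print(chs.metrics_table(results).round(3).to_string(index=False))
```

```
constituent pretreatment  LV   R2c  RMSEC  RMSECV  RPDcv   R2p  RMSEP  RPDp  slope   bias
         FI          snv   1 0.378  0.286   0.290  1.251 0.399  0.279 1.280  0.381 -0.043
         TP          snv   3 0.770 26.538  27.722  2.000 0.679 25.598 1.751  0.754 -0.979
         AA          snv   2 0.596 73.322  75.332  1.535 0.502 76.380 1.424  0.511  0.387
```

Each row is one calibration: `LV` is the cross-validated latent-variable
count; `R2c`/`RMSEC` are calibration-set fit, `RMSECV`/`RPDcv` the
leave-one-bean-out cross-validation error, and `R2p`/`RMSEP`/`RPDp` the
external validation performance (102 spectra from held-out beans), with the
regression slope and mean bias of predicted vs reference. The landscape
mirrors the real-bean study: TP predicts best (RPD ≈ 1.8, screening
quality), AA follows through its strong TP correlation, and FI is clearly
the weakest — its chemical image is illustrative rather than quantitative.

Per-pixel chemical maps come from applying a fitted model to a cleaned
hypercube:

```python
image = chs.predict_map(results[1].model, cube, labels, units="mg/g")
summary = chs.bean_level_summary(image, labels, panel=scene.bean_table)
chs.render_map(image, "tp_map.png", labels=labels, references=summary)
```

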