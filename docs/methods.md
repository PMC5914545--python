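# Methods

`cocoahsi` re-creates, end to end and on synthetic data, a single-seed
near-infrared hyperspectral imaging (NIR-HSI) calibration study on cocoa
beans: push-broom SWIR hypercubes of shelled beans are converted to
absorbance, cleaned, segmented into individual beans, reduced to per-bean
mean spectra, and used to build PLS1 calibrations for three quality
constituents — fermentation index (FI, the A460/A530 absorbance ratio of an
acidified methanol extract), total polyphenols (TP, mg ferulic-acid
equivalent g⁻¹) and antioxidant activity (AA, mmol Trolox equivalent kg⁻¹,
ABTS/QUENCHER). Fitted models are finally applied at single-pixel level to
produce chemical images.

No public dataset exists for this design, so the package ships a first-class
synthetic-data generator whose defaults encode the study conditions: 17
batches × 10 beans, each bean imaged on two sides (340 mean spectra), bean
chemistry following the published descriptive statistics and correlations.

## Reference panel generator

Bean-level (FI, TP, AA) triplets are drawn from a **zero-truncated
trivariate normal** with a batch-level mean shift:

    bean = μ + δ_batch + ε,   δ_batch ~ N(0, f·Σ),  ε ~ N(0, (1−f)·Σ)

with target moments μ = (0.98, 68.4, 186.1), SDs (0.34, 54.5, 116.1),
pairwise correlations r(TP,AA) = 0.876, r(FI,TP) = −0.570,
r(FI,AA) = −0.443 (positive definite, det ≈ 0.154, used directly), and
between-batch variance fraction f = 0.5 (a modelling choice: the published
batch plots show wide inter-batch spread but give no numeric decomposition;
`between_batch_fraction` is a config field).

Truncation at zero is by **resampling, never clipping**, to preserve the
correlation structure: an out-of-bounds bean has its within-batch residual
redrawn while keeping its batch shift. Two technical points:

* **Moment matching.** The TP marginal has SD/mean ≈ 0.8, so the parent
  (pre-truncation) normal that reproduces the Table-level moments after
  truncation is itself heavily truncated (parent TP mean is negative).
  Naively truncating a normal with the target moments would inflate the TP
  mean by ~16%. The generator therefore calibrates the parent parameters
  once per parameter set: univariate marginals are solved with the
  closed-form truncated-normal moment equations, then a damped fixed-point
  iteration on simulated moments absorbs the joint (cross-variable and
  hierarchical) truncation effects. The calibration is deterministic (fixed
  internal seed, independent of user seeds) and cached; residual bias is
  ≤ ~0.3% on means/SDs and ≤ 0.005 on correlations.
* **Pathological batches.** A batch shift deep in the lower tail can make
  residual resampling arbitrarily slow. Beans that do not accept within 150
  rounds fall back to privately redrawing shift and residual together. This
  preserves the bean-level marginal exactly and only weakens within-batch
  correlation in those rare batches. The realised acceptance rate is stored
  in `panel.attrs["acceptance_rate"]` (~0.2 at the defaults).

Because batches cluster (f = 0.5), moments estimated from a panel of B
batches of 10 carry a design effect of ≈ 1 + 9f on the mean's variance;
moment-recovery checks therefore draw beans one per batch (the bean-level
marginal is identical by construction), which tests the distribution at the
i.i.d. rate.

## Scene model

Per-pixel absorbance follows Beer–Lambert mixing over a small endmember
library on the camera's 240-band 1000–2495 nm axis:

    A(λ) = baseline(λ) + Σ_k c_k · E_k(λ)

Endmembers are sums of Gaussian bands at the literature assignments: lipid
1724/1743 and 2307/2326 nm, water/carbonyl 1919 nm, carbohydrate 1208/1340
nm, phenolic ~1420/1660 nm, anthocyanin ~1440 nm. Concentrations:
`c_phenolic ∝ TP`; `c_anthocyanin ∝ exp(−(FI−0.98)/0.34)`, strictly
decreasing in FI (anthocyanins degrade over fermentation — this is what the
FI assay actually measures); lipid, water/carbonyl and carbohydrate are
constant bulk components with 5% per-bean jitter. **AA has no endmember of
its own**: it is predictable only through its correlation with TP's phenolic
signal, mirroring the chemistry rationale that polyphenols are the dominant
antioxidant source. Consequently the AA model's validation R² is bounded by
r(TP,AA)² times the TP model's, a structural property of this design.

Raw 14-bit counts are generated as

    raw = dark + gain · (white − dark) · 10^(−A) + offset + N(0, σ_counts)

with per-(line, sample) multiplicative gain (lognormal, σ = 5%; spectrally
flat scatter of exactly the kind SNV removes), additive offset (σ = 20
counts), Gaussian count noise (σ = 30 counts), and whole-column detector
defects (2 dead + 1 hot element per scene, zeroed/saturated across all
lines). Beans are non-overlapping axis-aligned ellipses, ten per frame in
two rows of five on a 64 × 160 px frame (0.109 mm/px; full frames are 320 px
wide, the default crops to the tray). Geometry, levels and noise magnitudes
are all `SceneParams`/`SceneGeometry` fields; `SceneParams.noiseless()`
switches every stochastic term off, giving exact forward/inverse round
trips.

**Surface–assay coupling.** The camera sees a bean's surface; the reference
assays grind the whole bean. The default noise configuration therefore adds
a per-(bean, side) coupling error between the chemistry driving the spectra
and the reference value: σ = 30 mg/g for TP and σ = 0.50 for FI. These were
fixed so that the synthetic campaign reproduces the *published performance
landscape* — validation R² ≈ 0.7 for TP, AA below TP by the correlation
bound, and FI clearly weakest (the published study found FI ≈ 0.50 vs
TP 0.70 / AA 0.74) — rather than the near-perfect recovery the noiseless
configuration gives.

What the generator does **not** emulate: bean curvature shading, specular
highlights, shell/nib optics, wavelength-dependent scatter, touching beans,
and any real within-bean chemical gradient (an optional smooth gradient
exists but defaults to off). Passing recovery tests therefore show the
pipeline's correctness and the calibration machinery's behaviour under
controlled scatter/noise, not field performance on real beans.

## Processing chain

* **Absorbance**: R = (raw − dark)/(white − dark), clamped to [1e−4, 1.5]
  (floor prevents infinite absorbance on dead pixels; ceiling admits mild
  >1 reflectance from noise; clamp events are counted in metadata), then
  A = −log10 R. Dark subtraction doubles as the baseline correction.
* **Bad pixels** (the published pipeline names the step but not the method;
  these rules are this package's own): *dead* columns — zero variance along
  lines at the clamp floor; *hot* columns — negative absorbance (counts
  above white) in >50% of lines; *spikes* — single-band local extrema whose
  one-sided differences exceed 6 robust SDs **and** 0.5 AU (the absolute
  floor keeps smooth absorption-band curvature from triggering on low-noise
  scenes). Replacement is the median of valid 4-neighbours in the
  (sample, band) detector plane; the filter is idempotent. Scenes with >20%
  defective elements are rejected.
* **Band crop**: wavelengths below 990 nm are dropped (no useful signal from
  this detector below that edge).
* **Segmentation**: Otsu threshold on the band-mean absorbance image (beans
  are strong absorbers against the stage; a fixed threshold can be passed
  for regression tests), hole filling, 8-connectivity labelling, minimum
  area 50 px, objects ordered row-major by centroid (ascending centroid
  line, then sample). Side A/B identity comes from the scan manifest, not
  imagery.
* **Mean spectra**: unweighted pixel mean per object per band.

## Chemometrics

* **Split**: within each batch, round(0.7 · n) beans (half-up — exactly 7 of
  10, giving 238/102 spectra) are randomly assigned to calibration; both
  sides of a bean always share its role.
* **PLS1**: NIPALS on mean-centred, unscaled data; weights w = X'y/‖X'y‖,
  scores t = Xw, loadings p = X't/t't, q = y't/t't, deflation after each
  component; the regression vector b = W(P'W)⁻¹q plus intercept predicts in
  original units and is verified against the score recursion (≤1e−8).
  Requesting more components than the centred rank is an error naming the
  achievable rank; inside cross-validation, rank exhaustion in a fold
  instead freezes the regression vector (the CV curve goes flat, matching
  the behaviour expected on exactly low-rank noiseless data).
* **Cross-validation**: full leave-one-bean-out (a bean's two sides leave
  together, preventing side-leakage; per-spectrum LOO is available by
  passing per-row groups). RMSECV is aggregated over all held-out
  predictions; the LV count at the global minimum is selected, ties broken
  toward fewer LVs (parsimony).
* **Metrics**: R² is the *squared Pearson correlation* of reference and
  prediction (the convention of the chemometric software the procedure
  mirrors); the explained-variance variant is exposed separately as
  `r2_explained_variance` to avoid confusion. RMSE, slope (prediction on
  reference), bias (mean error) and RPD = SD_ref/RMSE complete the suite,
  where SD_ref is the SD of the *evaluated subset's own* reference values
  (calibration SD for RPD_cv, validation SD for RPD_p — this convention
  reproduces the published RPDs exactly from the published SDs and RMSEs).
  RPD is undefined at zero RMSE: requesting it for perfect predictions
  raises; omitting `sd_ref` returns the other metrics.
* **Coefficient peaks**: the most influential wavelengths are read off the
  regression-coefficient vector as the largest-|b| local extrema.

## Pretreatments

Exactly one step by default (the published comparison lists them as
alternatives): log(1/R) as-is, L1 area normalisation (sum of absolute
values — well defined for derivative spectra), SNV with the sample SD (n−1),
or Savitzky–Golay (5 points, 2nd-order polynomial, derivative 0–2).
Derivatives are scaled by the physical band spacing (per nm, per nm²) so
coefficients are comparable across grids; the axis must be uniform to 0.1%.
Edges use mirror padding; polynomial preservation is exact in the interior
(mirror-padded edges follow the padded sequence and are validated against a
brute-force windowed-fit oracle instead). The pretreatment spec is attached
to every fitted model and serialised with it, so pixel-level prediction
always repeats the training pretreatment.

## Chemical imaging

Pixel spectra inside the label map are pretreated with the model's own spec
and pushed through b; background stays NaN. Per-bean values are unweighted
means of pixel predictions — for non-linear pretreatments (SNV) this differs
from predicting the bean-mean spectrum, and the summary always averages
pixel predictions. Predictions are not clipped to the calibration range;
out-of-range pixels are counted in metadata. The FI map should be treated as
illustrative only: the FI calibration is the weakest of the three, on real
beans as in this emulation.

## Problem sizes and determinism

Every stochastic step takes an explicit seed and is exactly reproducible.
The standard synthetic campaign is 17 batches × 10 beans × 2 sides = 68
scenes of 64 × 160 × 240 values; a full simulate-process-calibrate run
completes in well under a minute. Moment-recovery checks use 10,000 beans;
oracle-equivalence checks use small instances (12×6, 20×5, 50×60) where
brute-force enumeration is exact.

## Known limitations

* AA is structurally capped below TP (no dedicated endmember — see above),
  so the synthetic AA model cannot reach the published AA R² of 0.735
  unless TP is nearly perfect.
* The published LV counts (15, 16, 14, 11, 8) and exact R²/RMSE values
  depend on the authors' raw spectra, which were never deposited; this
  package reproduces the *procedure* and verifies it by parameter recovery,
  design arithmetic and the RPD identities, not by matching those numbers.
* The wet-lab modules implement only the assays' arithmetic (ratios, OLS
  standard curves, SE/CV), not their chemistry.
* The bad-pixel and segmentation procedures are declared substitutes for
  unpublished in-house code; thresholds are config keys.
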