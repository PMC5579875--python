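# Methods

`hsigrade` is a complete, reproducible pipeline for grading a three-grade
semi-dry sausage from near-infrared hyperspectral images.  Because no public
image archive exists for this problem, the package ships its own generative
model; every downstream method (calibration, denoising, splitting, wavelength
selection, classification) is implemented exactly as it would be for real
cubes and is validated against the synthetic ground truth.

## 1. Synthetic cube generator (`hsigrade.synth`)

### Spectral model

The instrument is modeled as a 256-band line-scan NIR camera.  The wavelength
axis is uniform with exactly 200 bands spanning [975.01, 1645.82] nm
(spacing ≈ 3.3709 nm); the remaining 56 bands pad the axis on both sides and
are discarded by `subset_bands` during analysis, emulating the usual practice
of trimming noisy sensor edges.

Each pixel spectrum is a linear mixture of four endmember reflectances —
lean meat, fat, binder, conveyor-belt background — where an endmember is a
flat baseline minus Gaussian absorption dips placed at standard NIR overtone
positions:

| endmember | baseline | features (center nm, width nm, depth) |
|---|---|---|
| lean | 0.58 | (995, 14, 0.05), (1075, 26, 0.09), (1300, 40, 0.10), (1450, 34, 0.22) |
| fat | 0.68 | (1160, 18, 0.07), (1210, 16, 0.13), (1402, 22, 0.10) |
| binder | 0.50 | (1450, 40, 0.08) |
| background | 0.05 | — |

Lean carries protein/water bands (N–H second overtone near 995 and
1056–1099 nm, amide combinations at 1254–1348 nm, water O–H near 1450 nm);
fat carries C–H second overtones (1160, 1210 nm) and a weak O–H dip near
1402 nm.  These positions are where a meat-grading study would assign its
selected wavelengths, so band-selection recovery can be judged physically.

### Composition and variability

Grades 1–3 have mean lean fractions 0.75 / 0.60 / 0.45 of the meat mix (a
fixed 0.10 binder share is held out first).  Variability enters at four
levels, each a separate configuration knob:

1. **Between-sample**: a sample's lean fraction is Beta-distributed around
   its grade mean with concentration 260 (SD ≈ 0.027 at the mid grade).
2. **Slice level**: sliced samples draw fractions with
   `slice_variance_multiplier = 2.5` times the intact between-sample SD
   (implemented by shrinking the Beta concentration), and a slice's mean is
   centered on its parent sausage's draw, so slices correlate with their
   parent.
3. **Within-sample marbling**: per-pixel lean fractions are Beta-jittered
   around the sample value (concentration 80).
4. **Scatter**: each sample receives a smooth additive baseline — a degree-2
   Chebyshev polynomial in wavelength with coefficient SDs
   (1, 0.6, 0.4) × `scatter_sd` (default 0.03).  Sliced samples also
   multiply `scatter_sd` by the slice-variance multiplier: a cut surface is
   rougher and less planar than an intact casing, so its scattering
   variability is larger.  This term is what makes the grade mean ± SD
   envelopes overlap in every band while the grades remain separable
   multivariately — the regime reported for real sausages — and what makes
   sliced models measurably worse than intact ones.

### Acquisition model

Raw digital numbers invert the reflectance calibration:

```
raw = dark + R · (white − dark) + ε,  ε ~ N(0, 5 DN)
```

with deterministic reference frames (`dark` = 100 DN plus a small along-scan
gradient, `white − dark` = a smooth spectral illumination profile peaking at
2500 DN).  With `noise_sd = 0`, applying Eq. (1) reproduces the simulated
reflectance exactly — an identity the tests rely on.  Intact samples are
elongated ellipses, slices are discs; background pixels use the background
endmember.  `simulate_dataset` writes everything as ENVI raster files
(uint16 BIL cubes, float32 references) plus a manifest CSV and per-sample
ground-truth masks.

The default dataset is 50 intact sausages per grade and 3 slices per sausage
(150 + 450 samples) at 50×30 pixels.

## 2. Cube I/O and calibration (`hsigrade.envi`, `hsigrade.cube`)

A minimal, dependency-free ENVI reader/writer supports BIL and BSQ
interleaves and data types 4/5/12 (float32/float64/uint16), preserving the
wavelength list and failing loudly on malformed headers.
`correct_reflectance` applies `(raw − dark)/(white − dark)` per pixel (or
per column after averaging along the scan axis, the line-scan convention);
`subset_bands` keeps a closed wavelength interval.

## 3. Spectrum extraction (`hsigrade.spectra`)

* **Segmentation**: Otsu's threshold on the band nearest 1100 nm (a high
  sample/background contrast band), then the largest connected component.
* **Denoising**: Daubechies-6 wavelet, 3 decomposition levels, soft
  universal threshold `σ̂ √(2 ln n)` with `σ̂ = MAD(finest detail)/0.6745`,
  symmetric boundary extension, applied to every pixel spectrum.
* **ROI mean**: denoised pixel spectra are averaged over the mask to one
  spectrum per sample.

`summarize_grades` reports grade mean spectra, SDs at second-derivative
extrema, and the overlap structure.

## 4. Chemometrics (`hsigrade.split`, `.preprocess`, `.selection`, `.models`)

* **Kennard–Stone split** (`kennard_stone_split`): deterministic
  farthest-point sampling on Euclidean distances, run per grade with
  calibration fraction 0.74 — giving 37/13 per grade for 50 intact samples
  and 111/39 for 150 slices.  Ties break to the lowest row index.
* **Savitzky–Golay second derivative**: window 7, polynomial order 3,
  `deriv=2`, step = mean axis spacing.
* **D2 selection** (`select_by_d2`): candidate bands are local extrema of
  the pooled mean second-derivative spectrum, ranked by between-grade range
  (max − min of grade means at that band), kept greedily subject to a
  5-band minimum separation; default k = 14.
* **RF elimination** (`select_by_rf`): per round, train `models_per_round`
  seeded forests (50 trees, 50 features per split), average impurity
  importances, drop the 20 lowest-importance bands; from 200 bands stopping
  at 20 this is exactly 9 rounds.  Survivors are ranked by a final
  importance round; for k = 1..20 the mean out-of-bag (OOB) error over
  `models_per_round` forests is computed on the top-k bands and the k with
  the smallest mean OOB error is kept (ties → smallest k).
* **OOB accounting** (`hsigrade._forest`): OOB error counts a sample as an
  error when the majority vote of the trees that did not see it is wrong
  *or* when every bootstrap contained it (no vote); vote ties break to the
  lowest class.  Votes are accumulated from each tree's out-of-bootstrap
  indices directly, so the same accounting can be reused incrementally.
* **SVM grid** (`GridSVC`): RBF SVC behind a standardizing pipeline;
  C and γ range over 2^e for e = −8, −7.2, …, 8 (21 values, exponent step
  0.8), selected by seeded stratified 5-fold cross-validation on the
  calibration set; ties break to the smaller C, then smaller γ.
* **RF grid** (`GridRFC`): trees ∈ {50, …, 500 step 50} × features-per-split
  ∈ {10, …, 100 step 10} (clamped to the band count), scored by mean OOB
  error over `n_repeats` seeded repeats.  The tree axis is swept with
  `warm_start` so each forest is grown once and snapshotted at every
  checkpoint — exactly equivalent to fitting each size from scratch, ~10×
  faster.  Ties break to fewer trees, then fewer features.
* **Evaluation** (`evaluate`): 3×3 confusion matrix over grades {1, 2, 3}
  and overall accuracy 100·trace/total, rounded half-up to 2 decimals.

## 5. Pipeline (`hsigrade.pipeline`, CLI `hsigrade`)

`run_full` runs both forms independently end-to-end: split → full-spectrum
SVM + RF → D2 and RF wavelength selection on the calibration set → reduced
SVM + RF → report tables (confusion matrices, selected wavelengths,
hyperparameters, data-reduction percentages; reducing 200 → 15 variables is
a 92.5 % data reduction).  All randomness derives from one master seed via
`SeedSequence` spawn keys, so runs are bit-reproducible.  The CLI exposes
`simulate`, `extract`, `select`, `train` and `run-all`; exit code 2 marks
validation errors, 3 runtime errors.

## Runtime scaling in tests and the acceptance script

Two defaults are compute-heavy at study scale: `SelectionConfig.models_per_round = 100`
forests per elimination round, and `GridRFC.n_repeats = 10` OOB repeats per
grid cell.  The test suite and `scripts/acceptance.py` reduce these to 4 and
3 respectively (noted inline) so the full run fits a single-CPU container
budget; both procedures are averages whose structure is unchanged by the
repeat count, and the structural claims (round counts, schedules,
determinism, tie-breaks) are tested exactly.

## Limitations

* Synthetic spectra are linear mixtures with Gaussian absorption features;
  real sausage spectra include nonlinear scattering and moisture effects.
  Directional claims (intact > sliced, overlap structure) transfer; absolute
  accuracies do not.
* The OOB bookkeeping reads each tree's bootstrap via scikit-learn's
  internal `_generate_unsampled_indices`; a major scikit-learn upgrade could
  require touching `hsigrade/_forest.py`.
* ENVI support covers the interleaves/dtypes the generator writes (BIL/BSQ,
  types 4/5/12), not the full format zoo.
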