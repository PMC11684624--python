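# Methods

## Problem setting

A contrast-enhanced planning CT (CE-pCT) overstates attenuation wherever
iodine is present. The pipeline converts a CE-pCT slice into the domain of
a dual-layer spectral scanner ("pseudo DECT"), removes the contrast there
with a learned image-to-image model, and maps the result back into the
planning frame. The package implements each stage as a pure function of
(input, parameters, seed), so every run is reproducible from its manifest.

## CT number calibration

Two scanners assign slightly different CT numbers to the same material.
The calibration is a pair of independent ordinary-least-squares lines
relating mean plug CT numbers of an electron-density phantom imaged on
both scanners, split at 0 HU. No continuity is enforced at the boundary:
the measured coefficients themselves are discontinuous there (the default
model jumps from −5.36 to +2.71 HU across 0), and a forced joint would
distort both branches. The boundary sample x = 0 belongs to the negative
branch.

The inverse is the exact per-branch algebraic inverse. Target values
inside the discontinuity gap (−5.3595, 2.7053] have no forward pre-image;
they are mapped to 0 HU, the nearest pre-image boundary, which keeps the
inverse monotone and affects fewer than ten integer HU values. Calibration
is applied to floating-point HU; rounding to integers (half away from
zero) happens only at export.

The default coefficients ship with the package; `fit` never overwrites
them silently — it returns a new fitted estimator.

## Domain transfer

Stage order: couch removal → crop/resample → bilateral denoise →
calibration → noise injection. Couch removal runs first so that the body
centroid (which centres the 350 mm crop) is not biased by the couch.

* **Couch removal.** Threshold at −430 HU, 8-connected component
  labelling, deletion of components below 7000 pixels, hole filling (the
  lungs), exterior set to −1024 HU. A couch that touches the body merges
  into one component and survives — a documented limitation of the
  size-filter approach.
* **Resampling.** The spectral grid is defined as 512 px spanning exactly
  350 mm (0.6836 mm pixels; the nominal "0.68 mm" is a rounded value —
  deriving spacing as 350/512 keeps the field of view exact). The crop
  window is centred on the body-mask centroid and clamped to the image.
  Interpolation is bilinear in both directions; the transfer record stores
  the window so the inversion can reinsert the converted block into an
  untouched copy of the original image.
* **Bilateral filter.** Range-kernel *variance* equals the degree of
  smoothing (109.2218 HU²), spatial σ = 2 px, window 2⌈2σ⌉+1 = 9 px,
  replicate padding. This mirrors the parameterisation of the MATLAB
  `imbilatfilt` reference the values were measured with; it is implemented
  directly (shift-and-weight) rather than through a library filter with a
  different parameterisation.
* **Noise.** White Gaussian noise with variance P/10^(SNR/10), where P is
  the mean squared intensity on the 0–4095 offset scale (HU + 1024). The
  offset scale matches the normalisation window and avoids the
  sign-cancellation pathologies of raw HU. Noise is the last stage, inside
  the body frame; the result is clamped back to [−1024, 3071].

## VNC-Net

The architecture is a depth-four 2D U-Net: four encoder
stages of UnetConv2D (two Conv3×3–BatchNorm–ReLU blocks) + 2×2 max-pool at
widths 32/64/128/256, a UnetConv2D bottleneck (width 512 — the stated
widths double per stage and the bottleneck width is unstated, so the
doubling is continued; it is configurable), a decoder of 2×2/stride-2
transposed convolutions with skip concatenation and UnetConv2D blocks, and
a final 1×1 convolution. Inputs are clamped to [−1024, 3071] and min–max
normalised as (HU + 1024)/4095. Defaults: MSE loss, Adam (default
moments), batch 20, learning rate 1e-4, 300 epochs, 10% centre-crop
augmentation (central 75%, resized back — the crop size is a free choice).

Because no GPU framework is used, the layers are pure NumPy with explicit
backpropagation (im2col convolutions; the input gradient is computed as a
full correlation with the spatially flipped kernel). Everything is float32;
training is deterministic given the seed. Batch-norm uses running
statistics at inference. An optional cosine learning-rate schedule with a
two-epoch warmup is available for short training budgets.

Weight initialisation is He-normal for all convolutions except the output
head, whose 1×1 kernel is scaled down by 100× so training starts from a
near-flat prediction. With a full-scale random head, early optimisation is
dominated by undoing the head's arbitrary projection, and short training
runs end in basins whose quality depends strongly on the random draw; the
near-zero head removes that dependence and, in the recovery experiment
below, turns an unreliable outcome into a consistent one.

## Synthetic data

* **Digital phantom.** A water-equivalent body disc (radius 130 mm)
  carrying 15 mm-radius plugs laid out on two rings, with per-plug means
  and SDs defaulting to the measured planning/spectral/pseudo-spectral
  values for the sixteen tissue plugs (two of each of lung inhale/exhale,
  adipose, breast, muscle, liver, trabecular bone, dense bone). ROIs use
  80% of the plug radius (12 mm). The nominal in-ROI pixel counts for
  this geometry (248 on the planning grid, 968 on the spectral grid) are
  approximate under any single inclusion convention; the package uses
  pixel-centre-inside-radius and tests against brute-force enumeration
  with tolerance toward the nominal counts.
* **Paired CE/VNC slices.** Elliptical body (40 HU) with two lung fields
  (−800), an abdominal organ (55), a vertebral body plus rib
  cross-sections (700), and an enhancing blood pool (cardiac chamber +
  descending aorta, base 50). The non-contrast slice is the base anatomy;
  the enhanced slice adds a per-slice ΔHU drawn from 110–250 HU
  (blood pool) and 30–120 HU (organ); bone receives exactly zero. The
  deltas are added sharp-edged so the returned masks partition the
  enhancement exactly; anatomy is smoothed (σ = 1 px) to emulate partial
  volume; independent Gaussian noise (σ = 10 HU, the soft-tissue noise
  level of the phantom tables) is added to both slices. Geometry is
  procedurally randomised per slice so a model cannot memorise one layout.
  What the generator does **not** emulate: realistic textures, contrast
  kinetics, beam hardening, or the spectral decomposition physics of a
  real scanner — passing the recovery tests shows the training machinery
  works, not that the model is clinically validated.
* **Planning-frame patients.** For round-trip tests, a smooth
  abdomen-like slice (liver/kidney contrast within ~150 HU, interior
  smoothed with σ = 3 px) whose body boundary is sharp, so the
  couch-removal threshold contour coincides with the intensity edge. A
  thorax variant with air-filled lungs exists; its steep lung gradients
  are measurably smoothed by the bilateral filter (up to a few HU), which
  is inherent to the method, so the ≤2 HU round-trip bound is stated for
  soft-tissue anatomy.
* **Couch fixture.** Exact-size body blob (the N grid points closest to a
  centre in an elliptical metric — connected by construction) plus a
  detached wide arc trimmed to an exact pixel count, for truth-mask
  comparisons and the component-size boundary.

## The enhancement-recovery experiment

Clinical-cohort accuracy figures require private patient datasets and a
treatment-planning system; the package instead validates the learning
machinery by parameter recovery: train on 200 synthetic 64×64 pairs with a fixed
+150 HU blood-pool enhancement for 30 epochs, then measure the mean
absolute residual against the noise-free non-contrast truth inside the
enhancing regions of held-out slices (untrained residual ≈ 150 HU).

Choices made for this experiment, and why:

* **Narrow encoder (4/8/16/32, bottleneck 64).** Wider models showed no
  recovery benefit at this training budget and cost quadratically more
  per step; the architecture contract is unchanged.
* **Batch 5, learning rate 1e-2, cosine schedule with warmup.** At 30
  epochs the default clinical settings (batch 20, lr 1e-4) are far from
  convergence; small batches give 1200 optimisation steps and the decay
  stabilises the endpoint.
* **Best-validation checkpoint on an enhancement-region metric.**
  Contrast removal appears early in training and can erode later, while
  global validation MSE keeps improving — so plain MSE selection picks
  the wrong epoch. The selection metric is the mean |prediction − target|
  over validation pixels where the input exceeds its target by 50 HU,
  computable from the validation pairs alone.

The acceptance test asserts that training reduces the enhancement-region
residual in at least 95% of ten seeds and that the mean residual of the
selected checkpoints is below 25 HU.

## Evaluation metrics

MSE, PSNR (peakval defaulting to the target's maximum), SSIM (scikit-image
windowed implementation with Gaussian weights; stabilising constants
(0.01·L)² and (0.03·L)² from the data range L; a single-window global mode
evaluates the three-term formula directly), and Pearson correlation — all
over an optional body mask. Masked metrics equal their unmasked value on
the extracted pixel vector. Volume metrics pool all masked voxels by
default; a per-slice aggregation (one value per slice, then averaged) is
available through `per_slice_report`.

Wilcoxon signed-rank: zeros dropped, ties mid-ranked, exact distribution
for n ≤ 25 without rank ties (verified against full 2ⁿ enumeration),
normal approximation otherwise; two-sided.

## Dosimetry

Dq% is the (100−q)th percentile of the masked doses with linear
interpolation between order statistics; VxGy uses an inclusive threshold;
HI = (D2% − D98%)/D50% (the ICRU-83-style definition matching the
D2/D50/D98 triplet). Gamma: global normalisation to the reference maximum,
points below the low-dose threshold excluded, search disc of radius 3×DTA
sampled every DTA/10 with bilinear interpolation of the evaluated grid,
boundary γ = 1 counts as a pass. Sub-pixel search positions outside the
evaluated grid are skipped.

## Problem sizes

Test-suite computations are sized for a single CPU: the recovery
experiment uses 200 training pairs at 64×64 over ten seeds; round-trip and
phantom-conversion tests run at the native 512×512 planning grid; gamma
oracles use 32–48 px fields. The full clinical-scale configuration
(512×512 training at widths 32–256, 300 epochs) is exposed through the
same interfaces.

## Known limitations

* The couch-removal size filter keeps a couch that touches the body.
* The bilateral filter biases steep interior gradients (lung boundaries)
  by a few HU; the noise-free round trip is ≤2 HU only for soft-tissue
  anatomy.
* The recovery experiment shows the pipeline can learn a known additive
  enhancement at reduced scale; it says nothing about generalisation to
  real contrast distributions.
* DICOM support covers plain CT series (rescale tags, pixel spacing,
  positions); DICOM-RT dose/struct objects are out of scope — dose grids
  are read from generic volume formats.
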