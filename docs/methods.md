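# Methods

This note documents the modelling choices, the simulator, the numerical
conventions and the known limits of `mvmdm`.

## Pipeline

A subject volume is treated as an ordered stack of 2D slices along the
first stored axis; NIfTI orientation metadata is ignored throughout (the
pipeline operates on raw slice stacks, and the phantom writer uses an
identity affine).  Preprocessing is deliberately minimal:

* **Slice selection.** A contiguous window of `n_keep` slices (default 88)
  is retained, centered in the stack: `start = floor((N − n_keep) / 2)`.
  End slices of a structural scan carry little anatomy, and centering
  discards equal numbers from both ends.  The window start is exposed as an
  override for protocols that fix other indices.
* **Normalization.** Per-volume min–max rescaling to [0, 1]; a constant
  volume maps to zeros.  Normalization is per volume, not per slice, so the
  inter-slice contrast profile — exactly what the energy feature encodes —
  is preserved.  The transform is idempotent and invariant to positive
  affine rescalings of the input, so scanner gain/offset differences are
  removed.

## Wavelet layer

The working wavelet is db1 (Haar), one analysis level, implemented via
PyWavelets with `periodization` boundary handling.  For the even slice
sizes used everywhere (256, or 64 in the scaled profile) no boundary
extension is actually exercised and the transform is exactly orthonormal:
subbands are exactly half-size, reconstruction is exact to machine
precision, and the squared coefficients conserve the input energy
(Parseval).  Periodization is fixed (rather than pywt's default symmetric
extension) so that odd-sized inputs still produce `ceil(n/2)` subbands and
keep the energy bookkeeping; this choice only matters off the reference
geometry.

Orientation convention: **CH** denotes variation *across rows*
(horizontal-edge content), **CV** variation across columns.  The pinned
worked value is `[[1,2],[3,4]] → CA 5, CH −2, CV −1, CD 0`, and the unit
tests verify the convention against an independent 2×2 block filter-bank
oracle.  Other wavelets (db2, sym2, coif1) are accepted for
subband/wavelet-ablation protocols but are not the default.

The frequency-domain ablation filter is an ideal radial mask applied in
the 2D FFT domain, with cutoffs in cycles per image.  Published ablations
of this kind quote cutoffs in Hz; spatial images have no time axis, so the
package maps cutoffs onto radial spatial-frequency bins instead.  The
"Nyquist radius" is defined as the largest radial frequency on the FFT
grid (attained at the corner of the half-spectrum), so a lowpass at that
cutoff is exactly all-pass.  Highpass always removes DC.

## Features

* **Energy.** `E = Σ_xy sqrt(Gx² + Gy²)` of a CD subband slice, with
  central differences in the interior and one-sided differences at the
  borders (`numpy.gradient`), the minimal operator that uses neighbouring
  pixels.  A Sobel stencil is selectable (`operator="sobel"`); it changes
  the scale of the energies but not the ordering between classes.  Energy
  is an unnormalized sum (arbitrary units); per-pixel normalization can be
  applied downstream if volumes of different sizes are mixed.
* **Mean fusion.** Pixel-wise arithmetic mean over a subject's CH stack;
  slice-permutation invariant and bounded by the per-pixel extremes.
* **Route binding.** The headline configuration binds CD→1D, CH→2D, CV→3D;
  the binding is a parameter (`--route-binding`) so any subband can be fed
  to any route for ablation grids.

For training, each route's feature array is standardized by a scalar
z-score fitted on the training set only (mean and SD over all entries).
Detail-subband features are small in magnitude; the scalar standardization
conditions the optimization without touching inter-subject structure.

## Architectures and training

The three route architectures are expressed declaratively and traced
symbolically (valid convolutions, stride 1: `out = in − k + 1`; pooling:
`out = floor(in / p)`; conv parameters `∏k · c_in · c_out + c_out`; dense
`n_in · n_out + n_out`; batchnorm 4 per channel, 2 trainable).  At the
reference input sizes the traces reproduce the published tables exactly
(flatten 1280 / 25088 / 193536; totals 88,385 / 3,305,089 with 448
non-trainable / 24,957,985), and `mvmdm check-architecture` verifies this
with no data dependency.  Two conventions are forced by those numbers:
convolutions are unpadded with stride 1 (128 → 126 under a 3×3 kernel),
and the 3D pooling kernel is (1, 2, 2) (depth 87 unchanged across
pooling).  The output head is a single sigmoid unit: a softmax over one
logit is degenerate, and the near-threshold decision semantics (label 1
iff p ≥ 0.5) require a probability.

Training uses a compact NumPy engine written for this package (explicit
backpropagation, Adam with lr 0.001, fused sigmoid + binary cross-entropy,
inverted dropout, channels-last layout).  All stochastic sources — weight
initialization (Glorot uniform), epoch shuffling, dropout masks — draw
from one seeded generator, so a fixed seed reproduces training exactly on
one device.  The engine's gradients are validated against central
finite differences for every layer family, in both training and eval
mode.

Batch normalization required one deliberate deviation from the common
framework default: with cohorts of tens of subjects and ~10–20 epochs, a
momentum-0.99 exponential running-moment estimate never converges and
eval-mode normalization is mis-calibrated (training accuracy 1.0 with
chance-level held-out accuracy).  The engine uses momentum 0.9 and, after
training, performs one full-batch calibration pass that sets the running
moments to the exact training-set activation statistics.  Checkpointing,
when a validation split is requested, selects the epoch with the lowest
validation loss.

Evaluation: stratified train/test splits and stratified k-fold
cross-validation (scikit-learn), deterministic per seed.  The
k-fold harness reports per-seed mean accuracy and SD across folds, the
standard seed-stability protocol.

## Ensemble and metrics

The ensemble label is the strict majority of the three route votes; with
three binary voters ties cannot occur.  For completeness the vote operation
is total: an even ensemble breaks ties on the mean predicted probability
against the threshold (documented extension, not used by the standard
pipeline).  Metrics take the disease class (1) as positive:
accuracy, precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), F1 = harmonic mean of precision and
sensitivity, reported as percentages rounded to two decimals for display
with full precision retained internally.  A metric with a zero denominator
is reported as undefined (`None`), never as 0.

## Phantom simulator

The generator emulates the statistical structure the pipeline assumes —
a disease class with systematically lower gradient-magnitude energy —
without attempting anatomical realism.  Each volume is:

* a dark background (0.05),
* a fixed-contrast circular rim (a crude skull), identical for all
  subjects and never scaled, which anchors the intensity range so that
  per-volume min–max normalization cannot cancel the class contrast,
* `n_blobs` ellipsoidal structures with thin linear edge ramps.  Blob
  geometry comes from a fixed template determined by the phantom geometry
  alone — the shared "anatomy" — with small per-subject jitter of position
  (SD 2% of the field of view), size (±10%) and brightness (±10%), plus a
  per-subject global gain (±15%).  Sharing the template is essential for
  the 2D route: mean fusion presumes that structure occupies consistent
  locations across subjects, as real anatomy does; fully independent
  placement averages the class signal away,
* additive Gaussian voxel noise (default SD 0.02 on the [0, 1] scale,
  i.e. a high-SNR structural scan), then clipping to [0, 1].

Class 1 scales every blob amplitude by `1 − effect`.  Because energy is a
sum of gradient magnitudes concentrated at the edge ramps, the expected
energy of a class-1 subject decreases strictly and monotonically in
`effect`; at `effect = 0` the label does not enter the generative process
at all, so the classes are exchangeable and any classifier is at chance.
The per-subject seed is derived from `(cohort_seed, subject_index)`, so
cohorts are reproducible while subjects are independent, and the label
does not perturb the random draws (two subjects differing only in label
share geometry exactly).

Default parameters: 88 slices of 256×256 (paper-scale geometry), 12
blobs, noise SD 0.02, effect 0.6 (the strong-separation study condition).
What the phantom does **not** model: anatomy, lesions, scanner noise
physics (bias fields, Rician noise, motion), inter-site effects.  Passing
tests on phantoms therefore demonstrate the pipeline's mechanics —
feature extraction, learnability of contrast-coded class differences,
calibration under the null — not clinical performance.

## Problem sizes and profiles

Two built-in profiles fix the geometry and epoch budget:

| profile | slices | slice size | subbands | epochs |
|---------|--------|------------|----------|--------|
| `paper` | 88     | 256        | 88×128×128 | 20   |
| `test`  | 16     | 64         | 16×32×32   | 12   |

The `test` profile is the package's own scaled study condition for
simulation work: end-to-end runs (40 training / 20 held-out subjects, all
three routes) complete in under two minutes on one CPU.  The architecture
pattern is unchanged under scaling; the 3D route keeps the longest prefix
of conv–pool blocks whose shape trace stays positive (three of the four
blocks at the `test` geometry).  The symbolic traces of the reference
(`paper`) architectures are asserted regardless of which profile is used
for training.

## Known limitations

* The engine is CPU-only and single-device; paper-scale 3D training
  (25M parameters on 88×128×128 volumes) is out of its intended range.
* Per-volume min–max normalization assumes the intensity extremes are
  comparable across subjects (in the phantom this is enforced by the rim);
  heavy-tailed clinical intensities would need robust rescaling upstream.
* Bias-field correction, skull stripping and tissue segmentation are
  assumed to have happened upstream; the package does not perform them.
* The vote fuses hard labels only; probability-weighted fusion and ROC
  analysis beyond the fixed 0.5 threshold are not implemented.
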