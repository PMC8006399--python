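# Methods

This note documents the models, conventions and design choices behind
`ecmquant`, and what the synthetic-data validation does and does not show.

## Axial orientation statistics

Fiber orientations are axial quantities on [−90°, +90): a fiber at θ and at
θ + 180° is the same fiber. All statistics therefore use the doubled-angle
construction. The mean fiber orientation of a histogram with frequencies
f(θ) over 1° bins centred at integer degrees −90..+89 is

    θ̄ = ½ · atan2(Σ f sin 2θ, Σ f cos 2θ),

mapped back into [−90, +90). An arithmetic mean is ill-defined here (a
distribution straddling ±90° would average to ~0°, perpendicular to every
fiber in it); the circular choice fixes that and is recorded in output
metadata. When the doubled-angle resultant length falls below 1e-6 the
distribution is isotropic for this purpose; the mean is conventionally 0°
and results carry a `degenerate` flag.

**Normalization.** Subtracting θ̄ from every bin angle and wrapping angles
outside [−90, +90) by ±180° re-expresses the histogram relative to its own
mean (angle α). It is implemented as an exact circular shift of the
frequency array by round(θ̄) bins: mass is conserved bin-for-bin, no
interpolation is introduced, and the axial mean of the result equals the
sub-degree rounding residual, hence is 0° within half a bin by
construction. Sub-degree shifts are deliberately not interpolated; at the
1° bin width the residual is negligible against the sampling noise of any
realistic histogram. Normalized distributions from replicates are combined
by the per-bin arithmetic mean.

**Orientation index.** For a normalized, mean-centred distribution,

    S = Σ f(α) · cos 2α  =  2 Σ f(α) cos²α − 1,

with α converted to radians. S = 0 for a perfectly random distribution,
S = 1 for a delta at the mean, and S < 0 for mass concentrated
perpendicular to the mean axis; these endpoint conditions define the
statistic as implemented. S is invariant under circular shifts of the raw
histogram (rotation of the sample), because normalization removes the
shift first.

**Group comparison.** Two normalized (typically replicate-averaged)
distributions are compared by a two-sided Mann–Whitney U test whose two
samples are the 180 per-bin frequencies of each distribution, using the
asymptotic normal approximation with tie correction (exact U is always
reported; fully tied inputs are returned with p = 1 rather than dividing
by a zero null variance). An alternative reading — reconstructing
frequency-weighted |α| observations as the samples — is available via
`mode="angles"`.

A caveat worth stating plainly: the per-bin frequencies within one
distribution are not independent observations, so the test is *not*
calibrated in the usual sense. Simulation under the null (two groups of 14
replicate histograms from the same concentration, averaged, 200
repetitions) shows the test to be strongly conservative — the empirical
type-I rate at α = 0.05 is ≈ 0 because the shared distribution shape
dominates the pooled ranking — while power for clearly different
concentrations (κ = 0 vs κ = 4) is ≈ 1. Small p-values from this procedure
are therefore trustworthy evidence of a difference; the procedure will not
manufacture false positives, but its p-values are not uniformly
distributed under the null.

## Orientation estimation

The binary fiber mask is thinned to one-pixel-wide 8-connected centerlines
(Zhang–Suen axial thinning). At every centerline pixel the local tangent is
read off the structure tensor: gradients are derivative-of-Gaussian filters
with σ = 1 px (plain finite differences on an aliased one-pixel line bias
the angle by several degrees; the σ-1 derivative kernel removes the
staircase bias while staying local), the tensor is averaged under a
Gaussian window of σ = 7 px, and the orientation is the eigenvector of the
smaller eigenvalue (the along-line direction). The window parameter is
interpreted as the Gaussian σ. The binding accuracy contract is ±2° on
rendered straight lines; measured interior error is ≲ 1°.

Angular convention: 0° = image x-axis, counter-clockwise positive (y up),
range [−90, +90), with −90° the canonical representative of the vertical
axis. Binning is round-half-up to integer degrees, with [+89.5°, +90°)
wrapping onto the −90° bin. Every skeleton pixel contributes exactly one
histogram count, so longer fibers weigh proportionally more; a per-fiber
weighting is not provided.

`estimate_orientations` accepts an optional `source` image for the tensor
field, defaulting to the skeleton itself. In the full pipeline the
pre-thinning mask should be passed: thinning algorithms may displace the
centerline by a pixel at staircase steps (none of the four standard
algorithms we tested is equivariant under 90° image rotation), and sampling
the mask's smooth orientation field at the skeleton pixels makes the
estimates insensitive to that displacement. With the mask as source, an
image and its 90°-rotated copy produce normalized histograms agreeing to
total-variation ≈ 0.01; with the skeleton as source the disagreement can
reach ≈ 0.07 purely from centerline jitter.

## Preprocessing

Contrast adjustment shifts intensities so the darkest pixel becomes 0
(idempotent; an optional flag additionally stretches the maximum to 255,
off by default since only the black point is part of the canonical
procedure). Despeckling is one pass of a 3×3 median filter with reflected
edge padding — the standard definition of the operation. Intensities stay
in floating point on the 0–255 scale internally and are rounded half-up on
export; 16-bit inputs are rescaled by dtype range to 0–255.

## Trainable pixel classification

Both pipeline arms share one classifier: a random forest (100 trees,
bootstrap per tree, seeded and therefore reproducible; the seed is a
required parameter recorded in the model) over multi-scale feature stacks.

* Grayscale stack (fiber vs. pore): raw intensity plus, at each scale σ ∈
  {1, 2, 4, 8} px, Gaussian-smoothed intensity, Gaussian gradient
  magnitude, the two Hessian eigenvalues, a σ-vs-2σ difference of
  Gaussians, and local variance under a Gaussian window — 25 planes. The
  set covers smoothness, edges and ridge-ness without ballooning the
  model.
* RGB stack (trichrome): the three raw channels; three stain-density
  planes from color deconvolution with a fixed Masson's-trichrome basis
  (methyl/aniline blue ≈ (0.7995, 0.5913, 0.1053), Biebrich
  scarlet–acid fuchsin ≈ (0.0999, 0.7374, 0.6680) in optical density,
  residual = unit cross product); and per scale, per channel, Gaussian and
  gradient-magnitude planes.

The feature configuration (mode, scales, plane names) is stored in the
model and re-verified at inference, so a model can never silently run on
mismatched features; models apply to images of any size. Binarization of
the fiber probability map uses threshold 0.5 with ties counting as fiber;
no morphological cleanup beyond despeckle is applied. Annotations are
accepted as a label-mask image (0 = unlabeled, value k = class index
k − 1) or as a `row,col,class` CSV with 0-based ids.

Collagen percentage is 100·N_collagen/(N_collagen + N_non-collagen) over
the per-pixel argmax class map; background is a learned class, not a white
threshold, and the percentage is invariant to the amount of background by
construction. An all-background image has no defined percentage and raises.

## Synthetic ground truth

The fiber generator renders straight anti-aliased segments (width 3 px by
default, lengths uniform in 60–180 px, 60 fibers on 256²) at angles drawn
from an axial von Mises law — von Mises on doubled angles, halved — over a
dark background (fiber 200, pore 40 gray levels), with additive Gaussian
noise (σ = 10 by default, up to σ = 20 in the held-out segmentation tests)
and optional salt-and-pepper speckle. It returns the exact sampled angles
and the pre-noise fiber mask. The trichrome generator builds a blob-shaped
tissue region (55% of the frame) from a thresholded Gaussian random field,
assigns an exactly controlled fraction of tissue pixels to collagen via a
second, finer field, and colors classes with Masson-like means (collagen
blue-dominant, non-collagen red-dominant, background near-white) plus
per-channel noise (σ = 8). Both generators are pure functions of their
spec, seed included.

What the phantoms do not emulate: fiber curvature, branching and
out-of-plane crossings; SEM charging, depth-of-field and texture inside
fibers; stain intensity gradients, nuclei and scanner color shifts.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under known geometry and noise, not field performance on any
particular instrument; on real data, classifier training images and
annotations remain the user's responsibility.

## Numerical choices and degenerate inputs

* Histograms have exactly 180 bins; normalized frequencies must sum to 1
  within 1e-9 (averaging preserves this to machine precision).
* Mean-orientation degeneracy threshold: doubled-angle resultant < 1e-6.
  Degenerate inputs normalize with shift 0 and a warning.
* Structure-tensor eigenvectors are taken from whichever of the two
  algebraic forms is better conditioned per pixel; exactly isotropic
  tensor pixels (no local structure) fall back to 0°.
* Empty masks thin to empty skeletons; empty skeletons yield empty sample
  lists; empty sample lists cannot form a histogram (error).
* Random-forest training requires at least one annotation per vocabulary
  class and errors otherwise; all randomness flows from explicit seeds.

## Problem sizes used in validation

The test suite runs on 256² phantoms, 1200–1500 annotations per class,
100-tree forests, 10,000-sample orientation ensembles for the
concentration sweep, and 200 simulation repetitions (14 replicate
histograms of 2000 samples per group) for the power/size study — sizes at
which every quantity checked is stable against its stated tolerance.
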