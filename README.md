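# ecmquant

Quantifying extracellular-matrix (ECM) dysregulation from micrographs.

Tumors remodel the fibrous ECM around them: collagen fibers align, and
collagen content shifts. `ecmquant` implements a desk-top analysis pipeline
for two routine, inexpensive imaging modalities:

* **SEM arm** — scanning electron micrographs of decellularized ECM are
  contrast-adjusted, segmented into fiber vs. pore with a trainable
  random-forest pixel classifier, despeckled, thinned to one-pixel fiber
  centerlines, and each centerline pixel's local orientation is estimated
  from a Gaussian-windowed structure tensor (window σ = 7 px). The result
  is a 180-bin axial orientation histogram over [−90°, +89°].
* **Statistics** — fiber orientations are *axial* (θ ≡ θ + 180°). Each
  histogram's mean fiber orientation is computed by angle doubling,
  θ̄ = ½·atan2(Σ f sin 2θ, Σ f cos 2θ), and subtracted from every bin
  angle, wrapping out-of-range angles back by ±180°. These *normalized*
  distributions f(α) (α = angle relative to the mean) can be superimposed,
  averaged over replicates (Σfᵢ/n per bin), summarized by the orientation
  index S = Σ f(α)·cos 2α ∈ [−1, 1] (0 = isotropic, 1 = perfectly
  aligned), and compared between experimental groups with two-sided
  Mann–Whitney *U* tests on the per-bin frequencies.
* **Trichrome arm** — Masson's-trichrome-stained sections (collagen blue,
  other tissue red) are classified per pixel into collagen / non-collagen
  / background by a three-class random forest over color, stain-deconvolved
  and multi-scale texture features; collagen content is
  100·N_collagen/(N_collagen + N_non-collagen), i.e. the collagen share of
  tissue pixels after background removal.

Because real micrographs are rarely shareable, the package ships synthetic
generators with exact ground truth (fibrous phantoms with axial von Mises
orientation laws; trichrome-like phantoms with a controlled collagen
fraction) that back the entire test suite.

## Worked example

Train a fiber classifier on one synthetic micrograph, then compare an
isotropic condition against an aligned one (5 replicate images per group):

```python
import numpy as np
import ecmquant as eq
from ecmquant.synthetic import FiberImageSpec, generate_fiber_image
from ecmquant.segmentation import sample_labels

train, _, train_mask = generate_fiber_image(
    FiberImageSpec(n_fibers=60, mu=10, kappa=2, noise_sigma=15, seed=11))
stack = eq.compute_feature_stack(eq.adjust_contrast_min_black(train))
labels = sample_labels(train_mask.astype(int), ("pore", "fiber"), 1500, seed=7)
model = eq.train_pixel_classifier([stack], [labels], seed=3)

def analyze(img):
    img = eq.adjust_contrast_min_black(img)
    mask = eq.binarize(eq.apply_pixel_classifier(model, img), "fiber")
    mask = eq.despeckle(mask.astype(float) * 255.0) > 127
    skel = eq.axial_thinning(mask)
    hist = eq.build_histogram(eq.estimate_orientations(skel, source=mask))
    return eq.normalize_distribution(hist)

groups = {}
for name, kappa in [("isotropic", 0.0), ("aligned", 4.0)]:
    reps = []
    for r in range(5):
        img, _, _ = generate_fiber_image(FiberImageSpec(
            n_fibers=70, mu=30.0 * r - 60, kappa=kappa, noise_sigma=10,
            seed=200 + r + (0 if kappa == 0 else 50)))
        reps.append(analyze(img))
    groups[name] = eq.average_distributions(reps)
    print(f"{name}: OI = {eq.orientation_index(groups[name]):.3f}")

res = eq.compare_distributions(groups["isotropic"], groups["aligned"])
print(f"Mann-Whitney U = {res.U:.0f}, p = {res.p_value:.3g}")
```

which prints

```
isotropic: OI = 0.211
aligned: OI = 0.930
Mann-Whitney U = 24795, p = 1.58e-18
```

The aligned group concentrates its normalized distribution near α = 0,
driving the orientation index toward 1, and the Mann–Whitney test on the
averaged per-bin frequencies flags the difference decisively. The
isotropic group's OI is positive rather than exactly zero: with 70 fibers
per image there is chance alignment in every replicate, and normalization
centres each replicate on its own chance mean.

The same steps are available from the shell (`ecmquant synth`, `ecmquant
preprocess`, `ecmquant segment`, `ecmquant orient`, `ecmquant stats`,
`ecmquant collagen`); histograms travel as 180-row `angle_deg,frequency`
CSV files.

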