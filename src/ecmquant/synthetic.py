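"""Synthetic ground-truth image generators.

Real SEM micrographs of decellularized extracellular matrix and trichrome-
stained sections are not bundled with the package, so validation runs on
synthetic phantoms with known truth:

* fibrous grayscale images -- straight anti-aliased fibers whose angles
  follow an axial von Mises law (mean ``mu``, concentration ``kappa``;
  kappa = 0 is the uniform/isotropic limit, ``kappa = inf`` pins every
  fiber at ``mu``), over a darker background, with additive Gaussian noise
  and optional salt-and-pepper speckle;
* trichrome-like RGB images -- a blob-shaped tissue region on a near-white
  background, split into collagen (blue-dominant) and non-collagen
  (red-dominant) patches with an exactly controlled collagen fraction.

All generators are pure functions of their spec (seed included), and every
truth object satisfies the invariants of the type it instantiates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .collagen import TRICHROME_CLASSES, ClassMap
from .distributions import wrap_axial

__all__ = [
    "FiberImageSpec",
    "TrichromeImageSpec",
    "sample_axial_von_mises",
    "generate_fiber_image",
    "generate_trichrome_image",
]


def _sample_axial(rng: np.random.Generator, n: int, mu: float, kappa: float) -> np.ndarray:
    if kappa == math.inf:
        return wrap_axial(np.full(n, float(mu)))
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size=n)
    # von Mises on the doubled angles, then halve: the standard axial family
    doubled = rng.vonmises(np.deg2rad(2.0 * mu), kappa, size=n)
    return wrap_axial(np.rad2deg(doubled) / 2.0)


def sample_axial_von_mises(n: int, mu: float, kappa: float, seed: int) -> np.ndarray:
    """Draw ``n`` axial angles (degrees in [-90, +90)) from an axial von Mises.

    ``kappa = 0`` degenerates to the uniform distribution; larger kappa
    concentrates mass around ``mu``.  Reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("concentration kappa must be >= 0")
    return _sample_axial(np.random.default_rng(seed), n, mu, kappa)


@dataclass(frozen=True)
class FiberImageSpec:
    """Recipe for a synthetic fibrous grayscale image.

    Default sizes and intensity levels emulate a contrast-adjusted SEM
    field of view: bright fibers a few pixels wide over a dark pore
    background with moderate sensor noise.
    """

    shape: tuple[int, int] = (256, 256)
    n_fibers: int = 60
    mu: float = 0.0          # mean fiber angle, degrees
    kappa: float = 0.0       # axial von Mises concentration; inf = all at mu
    fiber_width: float = 3.0
    length_range: tuple[float, float] = (60.0, 180.0)
    foreground: float = 200.0
    background: float = 40.0
    noise_sigma: float = 10.0
    speckle_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.fiber_width < 1:
            raise ValueError("fiber width must be >= 1 pixel")
        for v in (self.foreground, self.background):
            if not 0 <= v <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")


def generate_fiber_image(spec: FiberImageSpec):
    """Render a fibrous image; returns ``(image, true_angles, true_mask)``.

    Fibers are straight anti-aliased segments at angles drawn from the
    spec's axial law, centred at uniform random positions (segments
    extending past the frame are clipped).  The returned mask is the
    pre-noise fiber footprint and the angles are the exact sampled values.
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((h, w))       # fiber coverage in [0, 1]
    truth = np.zeros((h, w), dtype=bool)
    angles = _sample_axial(rng, spec.n_fibers, spec.mu, spec.kappa)

    half = spec.fiber_width / 2.0
    for theta in angles:
        th = np.deg2rad(theta)
        dr, dc = -math.sin(th), math.cos(th)  # row axis points down
        length = rng.uniform(*spec.length_range)
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        p0 = (r0 - dr * length / 2, c0 - dc * length / 2)
        p1 = (r0 + dr * length / 2, c0 + dc * length / 2)

        pad = half + 2
        rmin = max(int(math.floor(min(p0[0], p1[0]) - pad)), 0)
        rmax = min(int(math.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
        cmin = max(int(math.floor(min(p0[1], p1[1]) - pad)), 0)
        cmax = min(int(math.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
        if rmin >= rmax or cmin >= cmax:
            continue

        rr, cc = np.meshgrid(
            np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij"
        )
        t = np.clip((rr - p0[0]) * dr + (cc - p0[1]) * dc, 0.0, length)
        dist = np.hypot(rr - (p0[0] + t * dr), cc - (p0[1] + t * dc))
        cover = np.clip(half + 0.5 - dist, 0.0, 1.0)  # 1-px anti-aliased edge
        region = canvas[rmin:rmax, cmin:cmax]
        np.maximum(region, cover, out=region)         # fibers occlude
        truth[rmin:rmax, cmin:cmax] |= dist <= half

    img = spec.background + (spec.foreground - spec.background) * canvas
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    if spec.speckle_fraction > 0:
        hit = rng.random(img.shape) < spec.speckle_fraction
        img = np.where(hit, np.where(rng.random(img.shape) < 0.5, 0.0, 255.0), img)
    return np.clip(img, 0.0, 255.0), angles, truth


@dataclass(frozen=True)
class TrichromeImageSpec:
    """Recipe for a trichrome-like RGB image with known per-pixel class.

    Class colors follow Masson's trichrome: collagen blue-dominant,
    cytoplasm/muscle red-dominant, background near-white; per-channel
    additive Gaussian noise emulates scanner variation.
    """

    shape: tuple[int, int] = (256, 256)
    collagen_fraction: float = 0.3   # share of the tissue region
    tissue_fraction: float = 0.55    # share of the frame covered by tissue
    tissue_smoothness: float = 12.0  # blob scale of the tissue outline, px
    patch_smoothness: float = 6.0    # blob scale of collagen patches, px
    collagen_color: tuple[float, float, float] = (70.0, 85.0, 170.0)
    non_collagen_color: tuple[float, float, float] = (185.0, 75.0, 95.0)
    background_color: tuple[float, float, float] = (245.0, 243.0, 242.0)
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise ValueError("collagen fraction must lie in [0, 1]")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise ValueError("tissue fraction must lie in (0, 1]")


def generate_trichrome_image(spec: TrichromeImageSpec):
    """Render a trichrome-like image; returns ``(rgb_image, truth_classmap)``.

    The tissue region is a thresholded smooth Gaussian random field;
    collagen patches inside it are a second, finer field thresholded so
    that exactly ``round(c * n_tissue)`` pixels are collagen -- the truth
    class map therefore realizes the requested fraction to within one
    pixel.
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    blob = ndi.gaussian_filter(rng.standard_normal((h, w)), spec.tissue_smoothness)
    n_tissue = int(round(spec.tissue_fraction * h * w))
    order = np.argsort(blob, axis=None)[::-1]
    tissue = np.zeros(h * w, dtype=bool)
    tissue[order[:n_tissue]] = True
    tissue = tissue.reshape(h, w)

    patch = ndi.gaussian_filter(rng.standard_normal((h, w)), spec.patch_smoothness)
    tr, tc = np.nonzero(tissue)
    k = int(round(spec.collagen_fraction * len(tr)))
    pick = np.argsort(patch[tr, tc])[::-1][:k]

    labels = np.zeros((h, w), dtype=int)  # background = 0
    labels[tissue] = TRICHROME_CLASSES.index("non_collagen")
    labels[tr[pick], tc[pick]] = TRICHROME_CLASSES.index("collagen")

    colors = np.array(
        [spec.background_color, spec.non_collagen_color, spec.collagen_color]
    )
    img = colors[labels].astype(float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0), ClassMap(labels, TRICHROME_CLASSES)
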