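"""Skeleton-based fiber orientation estimation.

The binary fiber mask is reduced to one-pixel-wide centerlines by axial
thinning; at every centerline pixel the local tangent orientation is read
off the Gaussian-windowed structure tensor of the skeleton image, and the
resulting angles are binned into the 180-bin axial histogram over
[-90, +89] degrees.

Angular convention: 0 degrees is the image x-axis (columns), positive
angles counter-clockwise (with the y-axis pointing up in display
convention), range [-90, +90) with -90 the canonical representative of the
vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .distributions import OrientationDistribution, N_BINS, wrap_axial

__all__ = [
    "OrientationSample",
    "axial_thinning",
    "estimate_orientations",
    "build_histogram",
]

#: Default Gaussian window (sigma, pixels) for the structure tensor.
DEFAULT_WINDOW = 7.0

#: Sigma of the Gaussian-derivative gradient filters.  Plain finite
#: differences on an aliased one-pixel skeleton bias the orientation by
#: several degrees; a sigma-1 derivative-of-Gaussian removes the staircase
#: bias while keeping the estimate local.
GRADIENT_SIGMA = 1.0


@dataclass(frozen=True)
class OrientationSample:
    """One local fiber orientation: angle in degrees plus pixel location."""

    angle: float
    row: int
    col: int


def axial_thinning(mask) -> np.ndarray:
    """Thin a binary fiber mask to one-pixel-wide centerlines.

    Topology-preserving 8-connected thinning (Zhang-Suen); deterministic.
    An empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    return skeletonize(mask.astype(bool))


def estimate_orientations(
    skeleton, window: float = DEFAULT_WINDOW, source=None
) -> list[OrientationSample]:
    """Local tangent orientation at every skeleton pixel.

    The structure tensor of ``source`` (by default the skeleton image
    itself) is computed from derivative-of-Gaussian gradients and averaged
    under a Gaussian weighting window of scale ``window`` pixels; at each
    skeleton pixel the along-line direction is the eigenvector belonging to
    the smaller tensor eigenvalue.  Angles are mapped into [-90, +90)
    degrees with the convention documented in the module docstring.  On
    rendered straight lines the interior estimates are accurate to well
    within 2 degrees.

    In the full pipeline, pass the pre-thinning fiber mask as ``source``:
    thinning algorithms may displace the centerline by a pixel at
    staircases, and sampling the mask's smooth orientation field at the
    skeleton pixels makes the estimates insensitive to that displacement
    (in particular, equivariant under 90-degree image rotations).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    sk = np.asarray(skeleton).astype(bool)
    if sk.ndim != 2:
        raise ValueError("expected a 2-D skeleton image")
    rows, cols = np.nonzero(sk)
    if len(rows) == 0:
        return []

    if source is None:
        f = sk.astype(float)
    else:
        f = np.asarray(source).astype(float)
        if f.shape != sk.shape:
            raise ValueError("source image must be congruent with the skeleton")
    gr = ndi.gaussian_filter(f, GRADIENT_SIGMA, order=(1, 0))
    gc = ndi.gaussian_filter(f, GRADIENT_SIGMA, order=(0, 1))
    arr = ndi.gaussian_filter(gr * gr, window)
    arc = ndi.gaussian_filter(gr * gc, window)
    acc = ndi.gaussian_filter(gc * gc, window)
    a = arr[rows, cols]
    b = arc[rows, cols]
    c = acc[rows, cols]

    lam_min = 0.5 * (a + c) - np.sqrt(0.25 * (a - c) ** 2 + b * b)
    # two algebraic eigenvector forms for lam_min; each degenerates when its
    # own components vanish, so take whichever has the larger norm per pixel
    v1r, v1c = -b, a - lam_min
    v2r, v2c = c - lam_min, -b
    use_v2 = v2r * v2r + v2c * v2c > v1r * v1r + v1c * v1c
    vr = np.where(use_v2, v2r, v1r)
    vc = np.where(use_v2, v2c, v1c)
    degenerate = vr * vr + vc * vc < 1e-24
    vr = np.where(degenerate, 0.0, vr)
    vc = np.where(degenerate, 1.0, vc)

    # row axis points down, so negate for counter-clockwise-positive angles
    angles = wrap_axial(np.rad2deg(np.arctan2(-vr, vc)))
    return [
        OrientationSample(angle=float(t), row=int(r), col=int(ci))
        for t, r, ci in zip(angles, rows, cols)
    ]


def build_histogram(samples) -> OrientationDistribution:
    """Bin orientation samples into the normalized 180-bin axial histogram.

    Accepts a sequence of :class:`OrientationSample` or plain angles in
    degrees.  Each angle goes to the nearest-integer-degree bin (round
    half-up); angles in [+89.5, +90) wrap to the -90 bin.  Frequencies are
    counts divided by the total; the sample count is retained.
    """
    if isinstance(samples, np.ndarray):
        angles = samples.astype(float)
    else:
        samples = list(samples)
        if samples and isinstance(samples[0], OrientationSample):
            angles = np.array([s.angle for s in samples], dtype=float)
        else:
            angles = np.asarray(samples, dtype=float)
    if angles.size == 0:
        raise ValueError("cannot build a histogram from an empty sample list")

    a = wrap_axial(angles)
    idx = np.floor(a + 0.5).astype(int)  # round half-up to integer degrees
    idx[idx >= 90] = -90  # 89.5+ wraps onto the -90 bin
    counts = np.bincount(idx + 90, minlength=N_BINS)
    return OrientationDistribution(
        counts / angles.size,
        total_count=int(angles.size),
        normalized=True,
    )
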