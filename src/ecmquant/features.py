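"""Multi-scale per-pixel feature stacks for trainable pixel classification.

A pixel classifier sees each pixel as a feature vector summarizing local
intensity, edges, ridges and texture at several smoothing scales.  Two
builders are provided: :func:`compute_feature_stack` for grayscale SEM
micrographs and :func:`compute_rgb_feature_stack` for RGB brightfield
images of Masson's trichrome stains, which additionally carries stain
densities from color deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import separate_stains
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

__all__ = [
    "FeatureStack",
    "DEFAULT_SCALES",
    "compute_feature_stack",
    "compute_rgb_feature_stack",
    "TRICHROME_STAIN_MATRIX",
    "TRICHROME_STAIN_NAMES",
    "trichrome_stain_densities",
]

#: Default smoothing scales (pixels) spanning fine fiber edges to coarse texture.
DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)

# Optical-density (R, G, B) absorption vectors for Masson's trichrome, from
# the standard colour-deconvolution literature values: methyl/aniline blue
# (collagen) and Biebrich scarlet-acid fuchsin (cytoplasm/muscle); the third
# row is the unit residual (cross product), completing an invertible basis.
_ANILINE_BLUE = np.array([0.7995, 0.5913, 0.1053])
_SCARLET_FUCHSIN = np.array([0.0999, 0.7374, 0.6680])
_RESIDUAL = np.cross(_ANILINE_BLUE, _SCARLET_FUCHSIN)
_RESIDUAL /= np.linalg.norm(_RESIDUAL)

TRICHROME_STAIN_MATRIX = np.stack(
    [
        _ANILINE_BLUE / np.linalg.norm(_ANILINE_BLUE),
        _SCARLET_FUCHSIN / np.linalg.norm(_SCARLET_FUCHSIN),
        _RESIDUAL,
    ]
)
TRICHROME_STAIN_NAMES = ("aniline_blue", "scarlet_fuchsin", "residual")


@dataclass(frozen=True)
class FeatureStack:
    """An ordered set of per-pixel feature planes for one image.

    ``planes`` has shape (n_features, H, W); ``names`` records the fixed
    plane order; ``mode`` ("gray" or "rgb") and ``scales`` record the
    configuration so a trained model can recompute identical features at
    inference time.
    """

    planes: np.ndarray
    names: tuple[str, ...]
    mode: str
    scales: tuple[float, ...]

    def __post_init__(self):
        if self.planes.ndim != 3 or self.planes.shape[0] != len(self.names):
            raise ValueError("planes must be (n_features, H, W) matching names")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def pixel_features(self, rows, cols) -> np.ndarray:
        """Feature matrix (n_pixels, n_features) at the given coordinates."""
        return self.planes[:, rows, cols].T

    def as_matrix(self) -> np.ndarray:
        """All pixels as a (H*W, n_features) matrix, row-major."""
        n = self.planes.shape[0]
        return self.planes.reshape(n, -1).T


def _check_scales(scales) -> tuple[float, ...]:
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("need at least one smoothing scale")
    if any(s <= 0 for s in scales):
        raise ValueError("smoothing scales must be positive")
    return scales


def _gray_scale_planes(img: np.ndarray, sigma: float):
    """The six per-scale grayscale features at one smoothing scale."""
    gauss = ndi.gaussian_filter(img, sigma)
    grad = ndi.gaussian_gradient_magnitude(img, sigma)
    h = hessian_matrix(img, sigma=sigma, order="rc", use_gaussian_derivatives=True)
    eigs = hessian_matrix_eigvals(h)  # sorted descending
    dog = gauss - ndi.gaussian_filter(img, 2.0 * sigma)
    var = np.clip(ndi.gaussian_filter(img * img, sigma) - gauss * gauss, 0, None)
    return [
        ("gaussian", gauss),
        ("gradient_magnitude", grad),
        ("hessian_min", eigs[-1]),
        ("hessian_max", eigs[0]),
        ("difference_of_gaussians", dog),
        ("local_variance", var),
    ]


def compute_feature_stack(img, scales=DEFAULT_SCALES) -> FeatureStack:
    """Grayscale feature stack: raw intensity plus six planes per scale.

    Per scale sigma: Gaussian-smoothed intensity, Gaussian gradient
    magnitude, smaller and larger Hessian eigenvalues (ridge detectors),
    difference of Gaussians (sigma vs 2*sigma), and local intensity
    variance under a Gaussian window.  Plane order is deterministic.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    scales = _check_scales(scales)

    planes = [img]
    names = ["raw"]
    for sigma in scales:
        for name, plane in _gray_scale_planes(img, sigma):
            planes.append(plane)
            names.append(f"{name}_s{sigma:g}")
    return FeatureStack(
        planes=np.stack(planes), names=tuple(names), mode="gray", scales=scales
    )


def trichrome_stain_densities(img) -> np.ndarray:
    """Per-pixel stain densities (H, W, 3) by Masson's-trichrome deconvolution.

    The image (0-255 RGB) is converted to optical density and projected onto
    the fixed stain basis :data:`TRICHROME_STAIN_MATRIX`; white pixels have
    density ~0 in every stain channel.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    rgb01 = np.clip(img / 255.0, 0.0, 1.0)
    return separate_stains(rgb01, np.linalg.inv(TRICHROME_STAIN_MATRIX))


def compute_rgb_feature_stack(img, scales=DEFAULT_SCALES) -> FeatureStack:
    """RGB feature stack for trichrome classification.

    Planes, in fixed order: the three raw channels; the three deconvolved
    stain-density planes (aniline blue, scarlet-fuchsin, residual); then per
    scale and per channel a Gaussian-smoothed plane and a Gaussian gradient
    magnitude plane.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3 or img[..., 0].size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    scales = _check_scales(scales)

    channels = ("r", "g", "b")
    planes = [img[..., i] for i in range(3)]
    names = [f"raw_{c}" for c in channels]

    stains = trichrome_stain_densities(img)
    for i, sname in enumerate(TRICHROME_STAIN_NAMES):
        planes.append(stains[..., i])
        names.append(f"stain_{sname}")

    for sigma in scales:
        for i, c in enumerate(channels):
            planes.append(ndi.gaussian_filter(img[..., i], sigma))
            names.append(f"gaussian_{c}_s{sigma:g}")
        for i, c in enumerate(channels):
            planes.append(ndi.gaussian_gradient_magnitude(img[..., i], sigma))
            names.append(f"gradient_magnitude_{c}_s{sigma:g}")

    return FeatureStack(
        planes=np.stack(planes), names=tuple(names), mode="rgb", scales=scales
    )
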