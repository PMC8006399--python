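"""Image loading and micrograph preprocessing.

Two preprocessing steps are applied to SEM micrographs of decellularized
extracellular matrix before segmentation: a black-point contrast adjustment
(shift the darkest pixel to true black) and despeckling (one pass of a 3x3
median filter).  Intensities are held in floating point on the 0-255 scale
and rounded half-up only on export.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "load_image",
    "save_image",
    "adjust_contrast_min_black",
    "despeckle",
]

#: ITU-R BT.601 luminance weights, the classic grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def _check_gray(img) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    return img


def load_image(path, mode: str = "gray") -> np.ndarray:
    """Load a TIFF or PNG image as a float array on the 0-255 scale.

    Parameters
    ----------
    path:
        Path to an 8-bit or 16-bit grayscale, or 8-bit RGB, TIFF/PNG file.
    mode:
        ``"gray"`` returns a 2-D array (RGB inputs are converted with BT.601
        luminance weights); ``"rgb"`` returns an (H, W, 3) array (grayscale
        inputs have their channel replicated).

    16-bit inputs are linearly rescaled so the dtype range [0, 65535] maps
    onto [0, 255].
    """
    if mode not in ("gray", "rgb"):
        raise ValueError(f"mode must be 'gray' or 'rgb', got {mode!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise ValueError(f"could not read image {path!r}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path!r}")

    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[-1] != 3):
        raise ValueError(f"unsupported image layout with shape {arr.shape}")

    img = arr.astype(float)
    if arr.dtype == np.uint16:
        img *= 255.0 / 65535.0
    elif arr.dtype not in (np.uint8, np.dtype(bool)):
        # float or other input: assume already on the 0-255 scale
        pass
    if arr.dtype == np.dtype(bool):
        img *= 255.0

    if mode == "gray":
        if img.ndim == 3:
            img = img @ _LUMA
        return img
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img


def save_image(img, path) -> None:
    """Export a float image to an 8-bit PNG/TIFF, rounding half-up."""
    arr = np.asarray(img, dtype=float)
    out = np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def adjust_contrast_min_black(img, rescale: bool = False) -> np.ndarray:
    """Shift intensities so the darkest pixel becomes true black (0).

    Relative intensity differences are preserved; the maximum is left
    unchanged unless ``rescale`` is set, in which case the result is
    additionally stretched so the brightest pixel maps to 255.  Idempotent.
    """
    img = _check_gray(img)
    out = img - img.min()
    if rescale:
        mx = out.max()
        if mx > 0:
            out = out * (255.0 / mx)
    return out


def despeckle(img) -> np.ndarray:
    """One pass of a 3x3 median filter with reflected edge padding.

    This is the standard despeckle operation: isolated salt-and-pepper
    pixels are replaced by the median of their 3x3 neighborhood, leaving
    uniform regions untouched.
    """
    img = _check_gray(img)
    return ndi.median_filter(img, size=3, mode="reflect")
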