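"""Collagen-content quantification from Masson's trichrome stains.

Masson's trichrome renders collagen blue and other tissue red; a
three-class pixel classifier (collagen / non-collagen / background) is
applied to RGB brightfield images and the collagen percentage is the share
of collagen-positive pixels among all tissue pixels, i.e. after background
removal:

    percent = 100 * N_collagen / (N_collagen + N_non_collagen)

By construction the percentage is invariant to how much background the
field of view contains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .features import compute_rgb_feature_stack, trichrome_stain_densities  # noqa: F401
from .segmentation import PixelClassifierModel, apply_pixel_classifier

__all__ = [
    "TRICHROME_CLASSES",
    "CLASS_PALETTE",
    "ClassMap",
    "CollagenResult",
    "classify_trichrome",
    "collagen_percentage",
    "class_map_to_rgb",
]

#: Fixed three-class vocabulary; ids index into this tuple.
TRICHROME_CLASSES = ("background", "non_collagen", "collagen")

#: Rendering palette: collagen red, non-collagen blue, background white.
CLASS_PALETTE = {
    "collagen": (200, 30, 30),
    "non_collagen": (40, 60, 200),
    "background": (255, 255, 255),
}


@dataclass
class ClassMap:
    """Per-pixel class labels (0-based ids into ``class_names``)."""

    labels: np.ndarray
    class_names: tuple[str, ...] = TRICHROME_CLASSES

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 2:
            raise ValueError("class map must be 2-D")
        if lab.size and (lab.min() < 0 or lab.max() >= len(self.class_names)):
            raise ValueError("class id outside the vocabulary")
        self.labels = lab

    def count(self, cls: str) -> int:
        return int(np.sum(self.labels == self.class_names.index(cls)))


@dataclass
class CollagenResult:
    """Collagen percentage plus the per-class pixel counts behind it."""

    percent_collagen: float
    n_collagen: int
    n_non_collagen: int
    n_background: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "percent_collagen": self.percent_collagen,
                "n_collagen": self.n_collagen,
                "n_non_collagen": self.n_non_collagen,
                "n_background": self.n_background,
            },
            indent=2,
        )


def classify_trichrome(model: PixelClassifierModel, img) -> ClassMap:
    """Per-pixel argmax classification of a trichrome RGB image.

    The model must carry the three-class trichrome vocabulary and RGB
    feature configuration; grayscale input or a mismatched vocabulary is an
    error.  Deterministic given model and image.
    """
    if tuple(model.class_names) != TRICHROME_CLASSES:
        raise ValueError(
            f"model vocabulary {model.class_names!r} does not match "
            f"the trichrome classes {TRICHROME_CLASSES!r}"
        )
    pmap = apply_pixel_classifier(model, img)  # rejects non-RGB input
    return ClassMap(pmap.argmax(), TRICHROME_CLASSES)


def collagen_percentage(cmap: ClassMap) -> CollagenResult:
    """Collagen share of tissue pixels, background excluded from the denominator."""
    n_col = cmap.count("collagen")
    n_non = cmap.count("non_collagen")
    n_bg = cmap.count("background")
    if n_col + n_non == 0:
        raise ValueError(
            "collagen percentage undefined: image contains only background"
        )
    return CollagenResult(
        percent_collagen=100.0 * n_col / (n_col + n_non),
        n_collagen=n_col,
        n_non_collagen=n_non,
        n_background=n_bg,
    )


def class_map_to_rgb(cmap: ClassMap) -> np.ndarray:
    """Render a class map with the fixed palette, as a uint8 RGB array."""
    out = np.zeros(cmap.labels.shape + (3,), dtype=np.uint8)
    for k, name in enumerate(cmap.class_names):
        out[cmap.labels == k] = CLASS_PALETTE[name]
    return out
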