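"""Trainable per-pixel random-forest classification.

Sparse pixel annotations plus a multi-scale feature stack train a random
forest that maps every pixel of an image to class probabilities.  The same
machinery serves both pipeline arms: fiber/pore segmentation of SEM
micrographs and three-class trichrome classification.

Annotations come in two dialects: a label-mask image where 0 means
unlabeled and value k labels class index k-1, or a CSV of ``row,col,class``
with 0-based class ids (both row-major, origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureStack, compute_feature_stack, compute_rgb_feature_stack

__all__ = [
    "LabelSet",
    "PixelClassifierModel",
    "ProbabilityMap",
    "sample_labels",
    "train_pixel_classifier",
    "apply_pixel_classifier",
    "binarize",
    "save_model",
    "load_model",
]

SEM_CLASSES = ("pore", "fiber")

_MODEL_FORMAT_VERSION = 1


@dataclass
class LabelSet:
    """Sparse pixel annotations: coordinates plus 0-based class indices."""

    rows: np.ndarray
    cols: np.ndarray
    class_ids: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        if not (len(self.rows) == len(self.cols) == len(self.class_ids)):
            raise ValueError("rows, cols and class_ids must have equal length")
        if len(self.class_ids) and (
            self.class_ids.min() < 0 or self.class_ids.max() >= len(self.class_names)
        ):
            raise ValueError("class id outside the class vocabulary")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_mask(cls, mask, class_names: Sequence[str]) -> "LabelSet":
        """Annotations from a label-mask image (0 = unlabeled, k = class k-1)."""
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if mask.max(initial=0) > len(class_names):
            raise ValueError("label mask value exceeds the class vocabulary size")
        rows, cols = np.nonzero(mask)
        return cls(rows, cols, mask[rows, cols] - 1, tuple(class_names))

    @classmethod
    def from_csv(cls, path, class_names: Sequence[str]) -> "LabelSet":
        """Annotations from a ``row,col,class`` CSV with 0-based class ids."""
        df = pd.read_csv(path)
        for col in ("row", "col", "class"):
            if col not in df.columns:
                raise ValueError(f"label CSV missing column {col!r}")
        return cls(
            df["row"].to_numpy(),
            df["col"].to_numpy(),
            df["class"].to_numpy(),
            tuple(class_names),
        )


def sample_labels(
    class_image,
    class_names: Sequence[str],
    n_per_class: int,
    seed: int,
) -> LabelSet:
    """Draw up to ``n_per_class`` random annotations per class from a dense
    ground-truth class image (0-based ids).  Convenience for training on
    synthetic images with known truth."""
    class_image = np.asarray(class_image, dtype=int)
    rng = np.random.default_rng(seed)
    rows, cols, ids = [], [], []
    for k in range(len(class_names)):
        r, c = np.nonzero(class_image == k)
        if len(r) == 0:
            continue
        take = min(n_per_class, len(r))
        pick = rng.choice(len(r), size=take, replace=False)
        rows.append(r[pick])
        cols.append(c[pick])
        ids.append(np.full(take, k))
    if not rows:
        raise ValueError("class image contains no labeled classes")
    return LabelSet(
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(ids),
        tuple(class_names),
    )


@dataclass
class PixelClassifierModel:
    """A fitted random forest plus everything needed to reapply it.

    The feature configuration (mode, scales, plane names) used at training
    is recorded and re-checked at inference, so a model can never silently
    be applied with mismatched features.
    """

    estimator: RandomForestClassifier
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    mode: str
    scales: tuple[float, ...]
    seed: int
    n_trees: int


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, shape (H, W, n_classes)."""

    probabilities: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 3 or p.shape[-1] != len(self.class_names):
            raise ValueError("probabilities must be (H, W, n_classes)")
        self.probabilities = p

    def class_index(self, cls) -> int:
        if isinstance(cls, str):
            try:
                return self.class_names.index(cls)
            except ValueError:
                raise ValueError(f"unknown class {cls!r}") from None
        idx = int(cls)
        if not 0 <= idx < len(self.class_names):
            raise ValueError(f"class index {idx} out of range")
        return idx

    def argmax(self) -> np.ndarray:
        """Per-pixel most probable class index."""
        return np.argmax(self.probabilities, axis=-1)


def train_pixel_classifier(
    stacks: Sequence[FeatureStack],
    labels: Sequence[LabelSet],
    seed: int,
    n_trees: int = 100,
) -> PixelClassifierModel:
    """Fit a random forest on annotated pixels of one or more images.

    ``stacks`` and ``labels`` are aligned one-to-one.  Every class in the
    vocabulary must be annotated at least once across the training set;
    training is reproducible given ``seed``.
    """
    if len(stacks) == 0 or len(stacks) != len(labels):
        raise ValueError("stacks and labels must be non-empty and aligned 1:1")
    ref = stacks[0]
    vocab = labels[0].class_names
    xs, ys = [], []
    for stack, lab in zip(stacks, labels):
        if stack.names != ref.names or stack.mode != ref.mode:
            raise ValueError("all training stacks must share one feature configuration")
        if lab.class_names != vocab:
            raise ValueError("all label sets must share one class vocabulary")
        h, w = stack.image_shape
        if len(lab) and (
            lab.rows.min() < 0
            or lab.cols.min() < 0
            or lab.rows.max() >= h
            or lab.cols.max() >= w
        ):
            raise ValueError("annotation outside image bounds")
        xs.append(stack.pixel_features(lab.rows, lab.cols))
        ys.append(lab.class_ids)
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    present = set(np.unique(y).tolist())
    missing = [name for k, name in enumerate(vocab) if k not in present]
    if missing:
        raise ValueError(f"no annotations for class(es): {', '.join(missing)}")

    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed), n_jobs=1
    )
    rf.fit(x, y)
    return PixelClassifierModel(
        estimator=rf,
        class_names=vocab,
        feature_names=ref.names,
        mode=ref.mode,
        scales=ref.scales,
        seed=int(seed),
        n_trees=int(n_trees),
    )


def apply_pixel_classifier(model: PixelClassifierModel, img) -> ProbabilityMap:
    """Classify every pixel of an image with a trained model.

    The model's recorded feature configuration is recomputed on ``img``
    (which may have any size); a grayscale model refuses RGB input and
    vice versa.
    """
    img = np.asarray(img, dtype=float)
    if model.mode == "gray":
        if img.ndim != 2:
            raise ValueError("model was trained on grayscale features; got non-2-D input")
        stack = compute_feature_stack(img, model.scales)
    elif model.mode == "rgb":
        if img.ndim != 3 or img.shape[-1] != 3:
            raise ValueError("model was trained on RGB features; got non-RGB input")
        stack = compute_rgb_feature_stack(img, model.scales)
    else:
        raise ValueError(f"unknown feature mode {model.mode!r}")
    if stack.names != model.feature_names:
        raise ValueError("feature configuration mismatch between model and image")

    h, w = stack.image_shape
    proba = model.estimator.predict_proba(stack.as_matrix())
    # training guarantees every vocabulary class is present, so the
    # estimator's column order is 0..n_classes-1 already
    full = np.zeros((h * w, len(model.class_names)))
    for col, k in enumerate(model.estimator.classes_):
        full[:, int(k)] = proba[:, col]
    return ProbabilityMap(full.reshape(h, w, -1), model.class_names)


def binarize(pmap: ProbabilityMap, fiber_class="fiber", threshold: float = 0.5) -> np.ndarray:
    """Boolean mask where P(fiber_class) >= threshold (ties count as fiber)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    idx = pmap.class_index(fiber_class)
    return pmap.probabilities[..., idx] >= threshold


def save_model(model: PixelClassifierModel, path) -> None:
    """Persist a model to a single file (joblib container with metadata)."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "estimator": model.estimator,
            "class_names": model.class_names,
            "feature_names": model.feature_names,
            "mode": model.mode,
            "scales": model.scales,
            "seed": model.seed,
            "n_trees": model.n_trees,
        },
        path,
    )


def load_model(path) -> PixelClassifierModel:
    """Load a model written by :func:`save_model`."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"not a recognized pixel-classifier model file: {path!r}")
    return PixelClassifierModel(
        estimator=payload["estimator"],
        class_names=tuple(payload["class_names"]),
        feature_names=tuple(payload["feature_names"]),
        mode=payload["mode"],
        scales=tuple(payload["scales"]),
        seed=payload["seed"],
        n_trees=payload["n_trees"],
    )
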