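import numpy as np
import pytest

import ecmquant as eq
from ecmquant.collagen import TRICHROME_CLASSES
from ecmquant.segmentation import sample_labels
from ecmquant.synthetic import (
    FiberImageSpec,
    TrichromeImageSpec,
    generate_fiber_image,
    generate_trichrome_image,
)

SEM_CLASSES = ("pore", "fiber")


@pytest.fixture(scope="session")
def sem_training():
    """A synthetic SEM-like training image with its ground-truth fiber mask."""
    spec = FiberImageSpec(n_fibers=60, mu=10.0, kappa=2.0, noise_sigma=15.0, seed=11)
    img, _, mask = generate_fiber_image(spec)
    return eq.adjust_contrast_min_black(img), mask


@pytest.fixture(scope="session")
def sem_model(sem_training):
    """A fiber/pore classifier trained on the synthetic SEM image."""
    img, mask = sem_training
    stack = eq.compute_feature_stack(img)
    labels = sample_labels(mask.astype(int), SEM_CLASSES, 1500, seed=7)
    return eq.train_pixel_classifier([stack], [labels], seed=3, n_trees=100)


@pytest.fixture(scope="session")
def trichrome_model():
    """A three-class trichrome classifier trained on a synthetic stain image."""
    img, truth = generate_trichrome_image(
        TrichromeImageSpec(collagen_fraction=0.4, seed=21)
    )
    stack = eq.compute_rgb_feature_stack(img)
    labels = sample_labels(truth.labels, TRICHROME_CLASSES, 1200, seed=8)
    return eq.train_pixel_classifier([stack], [labels], seed=4, n_trees=100)
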