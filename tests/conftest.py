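"""Shared fixtures.

The expensive fixtures are session-scoped: a 40-core processed study at
the generator defaults (used for the recovery checks) and a labeled
vessel set large enough for the 100-per-class training protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselphen.pipeline import simulate_and_process_cores
from vesselphen.simulate import ImageSimConfig, simulate_labeled_vessels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study40():
    """40 default-configuration cores, fully processed.

    Vessel class labels carry the ground-truth ("simulated pathologist")
    classes transferred by majority overlap.
    """
    records, truths = simulate_and_process_cores(40, seed=20240917)
    return records, truths


@pytest.fixture(scope="session")
def labeled_vessels():
    """250 labeled refined vessels per class at default shape parameters."""
    return simulate_labeled_vessels(250, seed=777)


@pytest.fixture(scope="session")
def small_core():
    """One small (512 px) default-density core, generated and processed."""
    from vesselphen.pipeline import process_core
    from vesselphen.simulate import generate_core_image

    config = ImageSimConfig(image_size=512, seed=42)
    stack, truth = generate_core_image(config)
    record = process_core(stack)
    return stack, truth, record


def random_connected_mask(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random connected blob: thresholded smooth noise, largest component."""
    from scipy import ndimage as ndi
    from skimage.measure import label

    field = ndi.gaussian_filter(rng.standard_normal((size, size)), rng.uniform(2, 6))
    mask = field > np.quantile(field, rng.uniform(0.6, 0.9))
    if not mask.any():
        mask[size // 2, size // 2] = True
    labels = label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest
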