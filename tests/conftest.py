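"""Shared fixtures: all test data is generated in memory or in tmp dirs."""

from __future__ import annotations

import numpy as np
import pytest

from segmetrics import LabelMask


@pytest.fixture
def toy_pair():
    """The 2x2 pair with one pixel in each confusion category."""
    truth = np.array([[1, 1], [0, 0]], dtype=bool)
    pred = np.array([[1, 0], [1, 0]], dtype=bool)
    return truth, pred


@pytest.fixture
def multiclass_pair():
    """3-class 2x2 label maps: class 1 perfect, class 2 missed, class 0 half."""
    truth = LabelMask(np.array([[1, 2], [0, 0]]))
    pred = LabelMask(np.array([[1, 0], [0, 2]]))
    return truth, pred


def random_mask_pair(rng: np.random.Generator, max_extent: int = 16):
    """A random boolean truth/pred pair of random shape up to max_extent."""
    shape = tuple(rng.integers(1, max_extent + 1, size=2))
    truth = rng.random(shape) < rng.uniform(0, 1)
    pred = rng.random(shape) < rng.uniform(0, 1)
    return truth, pred
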