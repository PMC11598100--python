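"""Shared fixtures: fitted pyramid kernels and the default simulated
paired acquisition (expensive, built once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from bstdmar.membrane import default_filters
from bstdmar.phantom import SimConfig, paired_dataset
from bstdmar.pipeline import decompose_stack


def smooth_field(rng: np.random.Generator, shape, sigma: float = 3.0) -> np.ndarray:
    """Random smooth image in [0, 1]."""
    f = ndimage.gaussian_filter(rng.uniform(0, 1, shape), sigma)
    return (f - f.min()) / (f.max() - f.min())


def random_blob_mask(rng: np.random.Generator, shape, margin: int = 12) -> np.ndarray:
    """Random disk-ish mask kept away from the image edge."""
    ny, nx = shape
    cy = int(rng.integers(margin + 4, ny - margin - 4))
    cx = int(rng.integers(margin + 4, nx - margin - 4))
    r = int(rng.integers(5, margin))
    yy, xx = np.mgrid[:ny, :nx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < r**2


@pytest.fixture(scope="session")
def filters():
    return default_filters()


@pytest.fixture(scope="session")
def paired_default():
    """The paired with/without-metal study dataset (256^2, 360 angles)."""
    return paired_dataset(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def decomp_default(paired_default):
    """Full-coverage decomposition of the with-metal stack."""
    cfg = paired_default["config"]
    S, U, masks, t_stack = decompose_stack(
        paired_default["with_metal"], threshold=10000, dilation=1, i0=cfg.i0
    )
    return {"S": S, "U": U, "masks": masks, "t": t_stack}
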