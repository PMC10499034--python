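"""Shared fixtures: small, fast synthetic stacks reused across test modules."""

import numpy as np
import pytest

from ciliaquant import synth
from ciliaquant.imagecore import Calibration, ImageStack


@pytest.fixture(scope="session")
def small_spec():
    """A 4x4-cell monolayer that generates in ~1 s."""
    return synth.MonolayerSpec(
        n_cells_x=4,
        n_cells_y=4,
        cell_diameter=8.0,
        cilium_length_range=(2.0, 3.0),
        seed=12,
    )


@pytest.fixture(scope="session")
def small_monolayer(small_spec):
    return synth.generate_monolayer(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_stack():
    """A constant single-channel stack (degenerate for thresholding)."""
    vox = np.full((1, 3, 40, 40), 7.0, dtype=np.float32)
    return ImageStack(
        voxels=vox,
        channel_names=["vesicles"],
        calibration=Calibration(0.21, 0.21),
        bit_depth=16,
    )
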