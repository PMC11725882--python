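import numpy as np
import pytest

import cvrnnseg as cv
from cvrnnseg import core, lattice


@pytest.fixture(scope="session")
def pipeline():
    """Shared default pipeline so connectivity matrices are built once."""
    return cv.Pipeline()


@pytest.fixture(scope="session")
def two_shape_image():
    return cv.make_shapes(2, seed=7)


def make_random_system(rng, n_side=None):
    """Small random lattice system with Gaussian connectivity and random omega."""
    if n_side is None:
        n_side = int(rng.integers(2, 7))
    spec = lattice.build_lattice(n_side)
    params = lattice.KernelParams(
        alpha=float(rng.uniform(0.1, 1.0)), sigma=float(rng.uniform(0.1, 1.0))
    )
    conn = lattice.gaussian_adjacency(spec, params)
    drive = core.InputDrive(rng.uniform(-2.0, 2.0, n_side**2))
    return core.compose_system(conn, drive)


def wrapped_phase_diff(a, b):
    """Absolute circular distance between phase arrays."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))
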