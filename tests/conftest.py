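import numpy as np
import pytest

from quadrf import (
    SpikeResponse,
    calibrate_scale,
    energy_model_cell,
    generate_gaussian,
    quadratic_logistic_cell,
    sample_spikes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_quadratic_dataset():
    """A D=6 quadratic-logistic cell with two strong kernel eigenvalues,
    N=20000 white-Gaussian bins, ~15% spike probability."""
    d = 6
    j = np.zeros((d, d))
    j[0, 0], j[1, 1] = -1.2, 0.9
    h = np.zeros(d)
    h[2] = 0.5
    cell = quadratic_logistic_cell(2.0, h, j)
    ens = generate_gaussian(20000, d, "white", seed=101)
    cell = calibrate_scale(cell, ens, 0.15)
    resp = sample_spikes(cell, ens, seed=102)
    return ens, resp, cell


@pytest.fixture(scope="session")
def small_energy_dataset():
    """A 4x4-pixel energy-model cell on white Gaussian patches."""
    ens = generate_gaussian(30000, 16, "white", seed=201)
    cell = calibrate_scale(energy_model_cell(4, 4, frequency=0.35, sigma=(1.2, 1.2)),
                           ens, 0.15)
    resp = sample_spikes(cell, ens, seed=202)
    return ens, resp, cell
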