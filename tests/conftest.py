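import numpy as np
import pytest

from dephenolize import (
    MLPSurrogate,
    ProcessBounds,
    SurfaceSpec,
    generate_design,
    make_default_spec,
    simulate_experiments,
)


@pytest.fixture(scope="session")
def bounds():
    return ProcessBounds()


@pytest.fixture(scope="session")
def default_spec():
    return make_default_spec()


@pytest.fixture(scope="session")
def noiseless_spec(default_spec):
    return SurfaceSpec(**{**default_spec.to_dict(), "noise_sd": 0.0})


@pytest.fixture(scope="session")
def noiseless_table(noiseless_spec, bounds):
    """33-run LHS table of exact surface values (seed 7)."""
    design = generate_design(bounds, 33, seed=7)
    return simulate_experiments(noiseless_spec, design, seed=7)


@pytest.fixture(scope="session")
def noisy_table(default_spec, bounds):
    """33-run LHS table with the default replicate noise (seed 7)."""
    design = generate_design(bounds, 33, seed=7)
    return simulate_experiments(default_spec, design, seed=7)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_table):
    """Best-of-10-inits 10-hidden surrogate on the noiseless table."""
    return MLPSurrogate(noiseless_table).fit_best(10, n_inits=10, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
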