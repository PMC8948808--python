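import numpy as np
import pytest

from emsckit import (
    MixtureScenario,
    SpectraSet,
    TwoGroupScenario,
    WavenumberAxis,
    make_mixture_series,
    make_two_group,
)


@pytest.fixture
def axis():
    """Small uniform axis for fast unit tests."""
    return WavenumberAxis(np.arange(1000.0, 1801.0, 10.0))  # 81 channels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_set(axis, rng):
    """Five random positive spectra on the small axis."""
    data = rng.uniform(0.1, 1.0, size=(5, len(axis)))
    return SpectraSet(axis, data, [f"s{i}" for i in range(5)])


@pytest.fixture(scope="session")
def two_group():
    """Default two-group dataset (seed 0): set, labels, truth."""
    return make_two_group(TwoGroupScenario(seed=0))


@pytest.fixture(scope="session")
def mixture():
    """Default mixture series (seed 0): set, concentrations, truth."""
    return make_mixture_series(MixtureScenario(seed=0))
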