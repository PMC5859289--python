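import numpy as np
import pytest

from shapegrowth import synthetic


@pytest.fixture(scope="session")
def toy_template():
    """Small ellipsoid template (86 vertices) plus its base configuration."""
    return synthetic.make_template(3)


@pytest.fixture(scope="session")
def tiny_template():
    """Minimal ellipsoid template (14 vertices)."""
    return synthetic.make_template(1)


@pytest.fixture(scope="session")
def rate_cohort():
    """Two groups on the same growth directions, group B at 1.5x the rate."""
    spec = synthetic.scenario("rate", resolution=3, seed=11)
    cohort, truth = synthetic.simulate_cohort(spec, 150, seed=12)
    return spec, cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Two groups drawn from one and the same trajectory."""
    spec = synthetic.scenario("null", resolution=2, seed=21)
    cohort, truth = synthetic.simulate_cohort(spec, 80, seed=22)
    return spec, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)
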