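import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cmlsched as cs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth1():
    """Reference synthetic parameter set (3 types: normal, WT, one mutant)."""
    return cs.synthetic_params(1)


@pytest.fixture(scope="session")
def scenario_m351t():
    return cs.load_fixture("table2_M351T")


@pytest.fixture(scope="session")
def maps8(synth1, scenario_m351t):
    """Affine month maps for an 8-month horizon on the reference set."""
    rates, dd = synth1
    stem = cs.make_stem_trajectory(scenario_m351t.x0, rates, dd, 8)
    return cs.precompute_affine_maps(rates, dd, stem, 8)


def random_state(rng, n_types=3, scale=1e6):
    """A random nonnegative system state with abundances spanning decades."""
    x = rng.uniform(0.0, 1.0, size=(4, n_types)) * scale * 10.0 ** rng.uniform(-2, 2)
    return cs.SystemState(x, 0.0)
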