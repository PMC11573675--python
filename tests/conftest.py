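import numpy as np
import pytest

from srcompose.fitting import ModelSpec
from srcompose.synthetic_data import simulate_cohort, uniform_sampler
from srcompose.task_graphs import build_protocol, make_factor


@pytest.fixture(scope="session")
def protocol4():
    """Default 4-cycle-prior session."""
    return build_protocol("prior4cycle", seed=11)


@pytest.fixture(scope="session")
def protocol6():
    """Default 6-cycle-prior session."""
    return build_protocol("prior6cycle", seed=12)


@pytest.fixture(scope="session")
def transfer_factors():
    f4 = make_factor("cycle", 4, ["A'", "B'", "C'", "D'"])
    f6 = make_factor("cycle", 6, [f"{i}'" for i in range(7, 13)])
    return f4, f6


@pytest.fixture(scope="session")
def m2_cohort_small():
    """Four M2 subjects (2 per condition) with moderate parameters."""
    sampler = uniform_sampler(
        alpha_prior=(0.1, 0.4),
        alpha_transfer=(0.1, 0.4),
        tau_exp=(0.1, 0.4),
        tau_inf=(0.1, 0.4),
    )
    return simulate_cohort(2, ModelSpec("M2", 2, 2), sampler, master_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
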