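"""Shared fixtures: short task configurations and tiny networks keep the
unit/property suite fast; trained-network fixtures live in
test_acceptance.py (session scope) because several acceptance checks share
them."""

import numpy as np
import pytest

from interareal.network import ArchitectureConfig, build_connectivity
from interareal.task import TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_task():
    """Task with abbreviated epochs (fast simulation, same structure)."""
    return TaskConfig(
        center_hold_mean=60.0, center_hold_sd=15.0,
        targets_min=80.0, targets_max=120.0,
        decision_len=300.0, stim_off_len=60.0,
    )


@pytest.fixture
def tiny_arch():
    return ArchitectureConfig(n_units=12, n_areas=3, rec_noise_sd=0.0,
                              ff_ee_density=1.0, fb_ee_density=1.0)


@pytest.fixture
def tiny_params(tiny_arch, rng):
    return build_connectivity(tiny_arch, rng)
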