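"""Shared fixtures: reference parameter sets and reusable simulation runs.

The heavier Monte Carlo ensembles are session-scoped so that unit,
property and acceptance tests share one run instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from polypull import PullingProtocol, Thermal

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from polypull.presets import apo_kinetics, holo_kinetics, octamer_construct
from polypull.pulling_simulator import mean_force_vs_speed, simulate_ensemble

BER_SPEEDS = [100.0, 200.0, 500.0, 1000.0, 2000.0, 4000.0]


@pytest.fixture(scope="session")
def thermal():
    return Thermal(298.0)


@pytest.fixture(scope="session")
def apo():
    return apo_kinetics()


@pytest.fixture(scope="session")
def holo():
    return holo_kinetics()


@pytest.fixture(scope="session")
def octamer():
    return octamer_construct()


@pytest.fixture(scope="session")
def protocol_1000():
    return PullingProtocol(speed=1000.0, cantilever_k=40.0)


@pytest.fixture(scope="session")
def apo_ensemble_1000(octamer, apo, protocol_1000):
    """500 apo traces at 1000 nm/s: the reference rupture-force ensemble."""
    return simulate_ensemble(octamer, apo, protocol_1000, n_traces=500, rng_seed=101)


@pytest.fixture(scope="session")
def holo_ensemble_1000(octamer, holo, protocol_1000):
    return simulate_ensemble(octamer, holo, protocol_1000, n_traces=500, rng_seed=102)


@pytest.fixture(scope="session")
def apo_speed_series(octamer, apo, protocol_1000):
    """Apo mean forces over the full speed range, 200 traces per speed."""
    return mean_force_vs_speed(
        octamer, apo, protocol_1000, BER_SPEEDS, n_traces=200, rng_seed=201
    )


@pytest.fixture(scope="session")
def holo_speed_series(octamer, holo, protocol_1000):
    return mean_force_vs_speed(
        octamer, holo, protocol_1000, BER_SPEEDS, n_traces=200, rng_seed=202
    )


@pytest.fixture(scope="session")
def recorded_apo_traces(octamer, apo, protocol_1000):
    """30 fully sampled apo traces for trace-analysis round trips."""
    return simulate_ensemble(
        octamer, apo, protocol_1000, n_traces=30, rng_seed=301, record=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
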