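"""Shared fixtures: baseline parameter set, calibrated uptake rates, and
session-scoped reference simulations reused across test modules."""
import numpy as np
import pytest

import interdiv as iv

D_CHEMOSTAT = 0.15
NU_BATCH = 0.276


@pytest.fixture(scope="session")
def kinetics():
    return iv.KineticParams()


@pytest.fixture(scope="session")
def division():
    return iv.DivisionLawParams()


@pytest.fixture(scope="session")
def kernel():
    return iv.KernelParams()


@pytest.fixture(scope="session")
def renewal(kinetics, division, kernel):
    return iv.RenewalModel(kinetics, division, kernel)


@pytest.fixture(scope="session")
def qS_chemostat(renewal):
    """Specific uptake rate giving a Malthusian rate equal to D."""
    return renewal.calibrate_qS(D_CHEMOSTAT)


@pytest.fixture(scope="session")
def qS_batch(renewal):
    """Specific uptake rate giving the batch log-phase growth rate."""
    return renewal.calibrate_qS(NU_BATCH)


@pytest.fixture(scope="session")
def chemostat_cfg(qS_chemostat):
    return iv.SimulationConfig(
        mode="chemostat", D=D_CHEMOSTAT, dt=0.01, n_init=3000,
        t_end=95.0, t_record_start=35.0, seed=20260915,
        kinetics=iv.KineticParams(qS_constant=qS_chemostat))


@pytest.fixture(scope="session")
def chemostat_run(chemostat_cfg):
    """Steady-state chemostat reference run (~3e4 division events)."""
    return iv.run_chemostat(chemostat_cfg)


@pytest.fixture(scope="session")
def batch_cfg(qS_batch):
    return iv.SimulationConfig(
        mode="batch", dt=0.01, n_init=1000, growth_factor=100.0,
        t_end=40.0, t_record_start=1.0, seed=20260916,
        kinetics=iv.KineticParams(qS_constant=qS_batch))


@pytest.fixture(scope="session")
def batch_run(batch_cfg):
    """Self-similar batch reference run (1e3 -> 1e5 cells)."""
    return iv.run_batch(batch_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
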