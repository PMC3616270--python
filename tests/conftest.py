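"""Shared fixtures: reference network and representative simulations.

Simulations are session-scoped — they are pure functions of the spec and
solver settings, so every test reads the same trajectory objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from larvacpg import (
    DriveProtocol,
    SolverSettings,
    default_network,
    simulate,
)


@pytest.fixture(scope="session")
def reference_spec():
    return default_network()


@pytest.fixture(scope="session")
def baseline_protocol():
    """Single forward-wave drive: strength 1.7 on the posterior segment, 2 t.u."""
    return DriveProtocol.single(8, 1.7, 0.0, 2.0)


@pytest.fixture(scope="session")
def baseline_trajectory(reference_spec, baseline_protocol):
    return simulate(reference_spec, baseline_protocol, 15.0)


@pytest.fixture(scope="session")
def fixed_step_settings():
    return SolverSettings(method="fixed_step", max_step=1e-3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130404)
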