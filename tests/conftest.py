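"""Shared fixtures: default machine/plan and session-scoped simulated series."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bpfqa import (
    BPFConfig,
    MachineModel,
    SimConfig,
    build_bpf_plan,
    simulate_delivery,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def machine() -> MachineModel:
    return MachineModel()


@pytest.fixture(scope="session")
def config() -> BPFConfig:
    return BPFConfig()


@pytest.fixture(scope="session")
def plan(machine, config):
    return build_bpf_plan(machine, config)


@pytest.fixture(scope="session")
def noisy_series(plan):
    """Default-noise simulated delivery shared by detection/PF/report tests."""
    return simulate_delivery(plan, SimConfig(seed=7))


@pytest.fixture(scope="session")
def clean_series(plan):
    """Noise-free single-frame-per-segment delivery (deterministic oracle)."""
    return simulate_delivery(plan, SimConfig(noise_rel=0.0, frames_per_segment=1))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
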