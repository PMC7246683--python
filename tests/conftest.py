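"""Shared fixtures: the three study parameter sets and sampler helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualsis import ModelParameters

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture
def s51_params() -> ModelParameters:
    """Bistable demand regime; sub-threshold offline transmission (R1 = 0.5)."""
    return ModelParameters(r1=1.0, r2=1.0, K1=1000.0, K2=1000.0, m=-1.2, n=-1.5,
                           beta11=0.000005, beta12=0.05, beta21=0.05, beta22=0.05,
                           gamma1=0.01, gamma2=0.01)


@pytest.fixture
def s52_params() -> ModelParameters:
    """Channel-2-dominant demand regime; online sweep base point."""
    return ModelParameters(r1=1.0, r2=1.0, K1=1000.0, K2=1000.0, m=-1.2, n=-0.5,
                           beta11=0.00005, beta12=0.00005, beta21=0.00005,
                           beta22=0.000005, gamma1=0.01, gamma2=0.01)


@pytest.fixture
def s53_params() -> ModelParameters:
    """Coexistence demand regime with strong cross transmission (Pi1 < Pi2)."""
    return ModelParameters(r1=1.0, r2=1.0, K1=1000.0, K2=1000.0, m=-0.8, n=-0.5,
                           beta11=0.00002, beta12=0.00005, beta21=0.00005,
                           beta22=0.00001, gamma1=0.01, gamma2=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
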