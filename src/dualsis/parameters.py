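"""Parameter containers, validation and configuration I/O.

The dual-channel model couples logistic demand growth in two sales channels
(offline = channel 1, online = channel 2) with SIS-type purchase transmission.
Twelve rate/capacity constants define a model instance:

=========  ==================================================================
r1, r2     intrinsic demand growth rates (per unit time)
K1, K2     channel carrying capacities (persons)
m, n       signed cross-influence of each channel's customer base on the
           other's demand growth (competition <=> m < 0 and n < 0)
beta11,
beta22     within-channel transmission influence rates (per contact per time)
beta12,
beta21     cross-channel transmission influence rates
gamma1,
gamma2     purchase-termination ("recovery") rates (per unit time)
=========  ==================================================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "SingleChannelParameters",
    "ModelParameters",
    "ValidationReport",
    "validate_parameters",
    "RunConfig",
    "load_config",
]

#: Absolute tolerance below which ``r1*r2 - m*n`` is treated as degenerate.
DEGENERACY_TOL = 1e-12


class ParameterError(ValueError):
    """Raised when a parameter set violates a hard invariant."""


@dataclass(frozen=True)
class SingleChannelParameters:
    """Constants of the single-channel SIS purchase model.

    ``beta`` is the transmission influence rate per contact per unit time,
    ``gamma`` the purchase-termination rate, and ``N`` the (constant) total
    population S(t) + I(t).
    """

    beta: float
    gamma: float
    N: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ParameterError("beta must be nonnegative")
        if self.gamma < 0:
            raise ParameterError("gamma must be nonnegative")
        if self.N <= 0:
            raise ParameterError("N must be positive")

    @property
    def reproduction_number(self) -> float:
        """Basic reproduction number R0 = beta*N/gamma."""
        if self.gamma == 0:
            raise ParameterError("R0 undefined for gamma = 0")
        return self.beta * self.N / self.gamma


@dataclass(frozen=True)
class ModelParameters:
    """The twelve constants of the dual-channel system."""

    r1: float
    r2: float
    K1: float
    K2: float
    m: float
    n: float
    beta11: float
    beta12: float
    beta21: float
    beta22: float
    gamma1: float
    gamma2: float

    @property
    def interior_denominator(self) -> float:
        """``r1*r2 - m*n``, the denominator of the interior demand equilibrium."""
        return self.r1 * self.r2 - self.m * self.n

    @property
    def competitive(self) -> bool:
        """True when both cross-influence rates are negative (channel competition)."""
        return self.m < 0 and self.n < 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def swap_channels(self) -> "ModelParameters":
        """Relabel channel 1 <-> channel 2 (used for symmetry checks)."""
        return ModelParameters(
            r1=self.r2, r2=self.r1, K1=self.K2, K2=self.K1,
            m=self.n, n=self.m,
            beta11=self.beta22, beta12=self.beta21,
            beta21=self.beta12, beta22=self.beta11,
            gamma1=self.gamma2, gamma2=self.gamma1,
        )

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        names = {f.name for f in fields(cls)}
        kwargs = {k: float(v) for k, v in data.items() if k in names}
        missing = names - kwargs.keys()
        if missing:
            raise ParameterError(f"missing parameters: {sorted(missing)}")
        return cls(**kwargs)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_parameters`.

    ``errors`` name the offending fields; ``flags`` record degeneracies that
    downstream computations must treat specially (they do not invalidate the
    parameter set).
    """

    params: ModelParameters
    errors: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_for_errors(self) -> ModelParameters:
        if self.errors:
            raise ParameterError("; ".join(self.errors))
        return self.params


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check hard invariants and flag downstream degeneracies.

    Hard invariants: K1, K2 > 0; r1, r2 > 0; all betas >= 0; gamma1, gamma2 > 0.
    ``m`` and ``n`` are unrestricted in sign.  Flags: ``r1*r2 - m*n`` within
    :data:`DEGENERACY_TOL` of zero (interior demand equilibrium undefined).
    """
    report = ValidationReport(params=params)
    for name in ("K1", "K2"):
        if getattr(params, name) <= 0:
            report.errors.append(f"{name} must be positive")
    for name in ("r1", "r2"):
        if getattr(params, name) <= 0:
            report.errors.append(f"{name} must be positive")
    for name in ("beta11", "beta12", "beta21", "beta22"):
        if getattr(params, name) < 0:
            report.errors.append(f"{name} must be nonnegative")
    for name in ("gamma1", "gamma2"):
        if getattr(params, name) <= 0:
            report.errors.append(f"{name} must be positive")
    if not any(math.isfinite(v) for v in (params.interior_denominator,)) or \
            abs(params.interior_denominator) <= DEGENERACY_TOL:
        report.flags.append("interior equilibrium undefined (r1*r2 - m*n ~ 0)")
    return report


@dataclass
class RunConfig:
    """A model instance plus an initial state and a time horizon."""

    params: ModelParameters
    state0: np.ndarray  # (N1, I1, N2, I2)
    t_end: float
    demographic_coupling: bool = True
    extra: dict[str, Any] = field(default_factory=dict)


_STATE_KEYS = ("N1_0", "I1_0", "N2_0", "I2_0")


def _parse_coupling(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in {"on", "true", "yes", "1"}:
            return True
        if lowered in {"off", "false", "no", "0"}:
            return False
    raise ParameterError(f"demographic_coupling must be on/off, got {value!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value config (YAML or JSON) into a :class:`RunConfig`.

    Recognised keys: the twelve parameter names, ``N1_0 I1_0 N2_0 I2_0``
    (initial state, purchased-customer seeds default to 0), ``t_end`` and the
    optional ``demographic_coupling: on|off`` model switch.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} does not contain a key-value mapping")
    params = ModelParameters.from_dict(data)
    state0 = np.array([float(data.get(k, 0.0)) for k in _STATE_KEYS], dtype=float)
    t_end = float(data.get("t_end", 100.0))
    coupling = _parse_coupling(data.get("demographic_coupling", True))
    known = set(f.name for f in fields(ModelParameters)) | set(_STATE_KEYS) | {
        "t_end", "demographic_coupling",
    }
    extra = {k: v for k, v in data.items() if k not in known}
    return RunConfig(params=params, state0=state0, t_end=t_end,
                     demographic_coupling=coupling, extra=extra)
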