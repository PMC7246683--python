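"""Right-hand sides, admissible regions and Jacobians of the channel dynamics.

Three nested systems are defined.

Single channel (classic SIS, closed population N = S + I)::

    dS/dt = -beta*S*I + gamma*I
    dI/dt =  beta*S*I - gamma*I

Two-dimensional demand system for the channel totals (N1, N2) — logistic
growth with Lotka–Volterra-type cross influence::

    dN1/dt = r1*N1*(1 - N1/K1) + m*N1*N2/K2
    dN2/dt = r2*N2*(1 - N2/K2) + n*N1*N2/K1

Four-dimensional purchase system for (N1, I1, N2, I2), coupling the demand
dynamics with mass-action purchase transmission within and across channels::

    dI1/dt = (beta11*I1 + beta12*I2)*(N1 - I1) - gamma1*I1 [+ g1*I1]
    dI2/dt = (beta21*I1 + beta22*I2)*(N2 - I2) - gamma2*I2 [+ g2*I2]

where g1 = r1*(1 - N1/K1) + m*N2/K2 and g2 = r2*(1 - N2/K2) + n*N1/K1 are
the per-capita demand growth rates.  The bracketed demographic terms carry
purchased customers along with the growth or shrinkage of their channel's
customer base; they vanish at every equilibrium studied by the analysis
modules and can be switched off (``demographic_coupling=False``).  With the
terms on, I_i <= N_i is forward-invariant: at I1 = N1,
d(I1 - N1)/dt = -gamma1*N1 <= 0.

The admissible regions are the boxes
G  = {(N1, N2): 0 <= Ni <= Ki} and
G' = {(N1, I1, N2, I2): 0 <= Ii <= Ni <= Ki}.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .parameters import ModelParameters, SingleChannelParameters

__all__ = [
    "sis_rhs_single",
    "per_capita_growth",
    "rhs_2d",
    "rhs_4d",
    "in_region",
    "jacobian_2d",
    "jacobian_4d",
    "REL_TOL",
    "ABS_TOL",
]

#: Default relative / absolute tolerances for region membership and
#: equilibrium verification.
REL_TOL = 1e-9
ABS_TOL = 1e-12


def sis_rhs_single(state: Sequence[float],
                   params: SingleChannelParameters) -> tuple[float, float]:
    """Time derivative (dS/dt, dI/dt) of the single-channel SIS model.

    The two components sum to zero identically, so S + I is conserved.
    """
    S, I = state
    flow = params.beta * S * I - params.gamma * I
    return (-flow, flow)


def per_capita_growth(N1: float, N2: float,
                      params: ModelParameters) -> tuple[float, float]:
    """Per-capita demand growth rates (g1, g2) at channel totals (N1, N2)."""
    g1 = params.r1 * (1.0 - N1 / params.K1) + params.m * N2 / params.K2
    g2 = params.r2 * (1.0 - N2 / params.K2) + params.n * N1 / params.K1
    return g1, g2


def rhs_2d(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Time derivative of the two-dimensional demand system at (N1, N2)."""
    N1, N2 = state
    g1, g2 = per_capita_growth(N1, N2, params)
    return np.array([N1 * g1, N2 * g2])


def rhs_4d(state: Sequence[float], params: ModelParameters,
           demographic_coupling: bool = True) -> np.ndarray:
    """Time derivative of the four-dimensional system at (N1, I1, N2, I2)."""
    N1, I1, N2, I2 = state
    g1, g2 = per_capita_growth(N1, N2, params)
    force1 = params.beta11 * I1 + params.beta12 * I2
    force2 = params.beta21 * I1 + params.beta22 * I2
    dI1 = force1 * (N1 - I1) - params.gamma1 * I1
    dI2 = force2 * (N2 - I2) - params.gamma2 * I2
    if demographic_coupling:
        dI1 += g1 * I1
        dI2 += g2 * I2
    return np.array([N1 * g1, dI1, N2 * g2, dI2])


def in_region(state: Sequence[float], params: ModelParameters,
              tol: float | None = None) -> bool:
    """Membership of G (2-vector) or G' (4-vector), with tolerance.

    Inequalities are tested within ``tol`` relative to the channel capacity
    (default :data:`REL_TOL`).
    """
    if tol is None:
        tol = REL_TOL
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    state = np.asarray(state, dtype=float)
    slack1 = tol * max(1.0, params.K1)
    slack2 = tol * max(1.0, params.K2)
    if state.shape == (2,):
        N1, N2 = state
        return (-slack1 <= N1 <= params.K1 + slack1
                and -slack2 <= N2 <= params.K2 + slack2)
    if state.shape == (4,):
        N1, I1, N2, I2 = state
        return (-slack1 <= I1 <= N1 + slack1 and N1 <= params.K1 + slack1
                and -slack2 <= I2 <= N2 + slack2 and N2 <= params.K2 + slack2
                and N1 >= -slack1 and N2 >= -slack2)
    raise ValueError(f"state must have length 2 or 4, got shape {state.shape}")


def jacobian_2d(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_2d` at (N1, N2)."""
    N1, N2 = state
    p = params
    return np.array([
        [p.r1 * (1.0 - 2.0 * N1 / p.K1) + p.m * N2 / p.K2, p.m * N1 / p.K2],
        [p.n * N2 / p.K1, p.r2 * (1.0 - 2.0 * N2 / p.K2) + p.n * N1 / p.K1],
    ])


def jacobian_4d(state: Sequence[float], params: ModelParameters,
                demographic_coupling: bool = True) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_4d` at (N1, I1, N2, I2).

    State ordering is (N1, I1, N2, I2); agrees with central finite
    differences of :func:`rhs_4d` to solver precision.
    """
    N1, I1, N2, I2 = state
    p = params
    c = 1.0 if demographic_coupling else 0.0
    g1, g2 = per_capita_growth(N1, N2, params)
    force1 = p.beta11 * I1 + p.beta12 * I2
    force2 = p.beta21 * I1 + p.beta22 * I2
    J = np.zeros((4, 4))
    # demand rows
    J[0, 0] = p.r1 * (1.0 - 2.0 * N1 / p.K1) + p.m * N2 / p.K2
    J[0, 2] = p.m * N1 / p.K2
    J[2, 0] = p.n * N2 / p.K1
    J[2, 2] = p.r2 * (1.0 - 2.0 * N2 / p.K2) + p.n * N1 / p.K1
    # purchased-customer rows
    J[1, 0] = force1 + c * I1 * (-p.r1 / p.K1)
    J[1, 1] = p.beta11 * (N1 - I1) - force1 - p.gamma1 + c * g1
    J[1, 2] = c * I1 * (p.m / p.K2)
    J[1, 3] = p.beta12 * (N1 - I1)
    J[3, 0] = c * I2 * (p.n / p.K1)
    J[3, 1] = p.beta21 * (N2 - I2)
    J[3, 2] = force2 + c * I2 * (-p.r2 / p.K2)
    J[3, 3] = p.beta22 * (N2 - I2) - force2 - p.gamma2 + c * g2
    return J
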