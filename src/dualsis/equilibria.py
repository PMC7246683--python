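"""Closed-form equilibria, thresholds and existence regimes.

Two-dimensional demand system: equilibria O(0,0), P(K1,0), Q(0,K2) always
exist in G; the interior point M = (N1E, N2E) with

    N1E = (m + r1)*r2*K1 / (r1*r2 - m*n)
    N2E = (n + r2)*r1*K2 / (r1*r2 - m*n)

exists (in the interior of G) only under channel competition (m, n < 0) in
one of two regimes:

* coexistence:  r1*r2 > m*n,  r1 > -m,  r2 > -n
* bistable:     r1*r2 < m*n,  r1 < -m,  r2 < -n

Four-dimensional system: P0(0,0,0,0), P1(K1,0,0,0), P3(0,0,K2,0) always
exist; the boundary endemic points P2(K1, I1E, 0, 0) and P4(0, 0, K2, I2E)
exist above the single-channel thresholds R1 = beta11*K1/gamma1 > 1 and
R2 = beta22*K2/gamma2 > 1, with Ii_E = Ki*(1 - 1/Ri); P5 = (N1E, 0, N2E, 0)
exists with M; and the interior endemic point P6 = (N1E, I1EE, N2E, I2EE)
exists when purchase transmission can invade P5, i.e. when

    Pi1 = (A - beta11*N1E) / (beta12*N1E)  <  Pi2 = beta21*N2E / (B - beta22*N2E)

with A = gamma1 - r1*(1 - N1E/K1) - m*N2E/K2 and B symmetric (at M these
reduce identically to A = gamma1, B = gamma2).  The Pi-criterion is
equivalent to the next-generation matrix at P5 having spectral radius > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import rhs_2d, rhs_4d
from .parameters import ModelParameters, ParameterError, validate_parameters

__all__ = [
    "EquilibriumPoint",
    "ThresholdSet",
    "classify_regime",
    "reproduction_numbers",
    "demand_equilibria_2d",
    "boundary_infected_equilibria",
    "interior_thresholds",
    "interior_infected_equilibrium",
    "enumerate_equilibria_4d",
    "equilibria_to_frame",
]

#: Strict regime inequalities closer than this to a boundary are "degenerate".
REGIME_TOL = 1e-12


@dataclass
class EquilibriumPoint:
    """A labelled equilibrium with coordinates and an existence verdict.

    ``reason`` names the violated condition when ``exists`` is False;
    ``condition_set`` records the inequality set that grants existence.
    """

    label: str
    coords: np.ndarray
    exists: bool
    reason: str | None = None
    condition_set: str = ""

    @property
    def dim(self) -> int:
        return len(self.coords)


@dataclass
class ThresholdSet:
    """Threshold quantities controlling equilibrium existence.

    R1, R2 are the single-channel basic reproduction numbers; A, B the
    infection balance terms at M (identically gamma1, gamma2 when M exists);
    Pi1, Pi2 the cross-transmission invasion ratios.  ``a_margin`` and
    ``b_margin`` are A - beta11*N1E and B - beta22*N2E.
    """

    R1: float
    R2: float
    regime: str
    A: float = math.nan
    B: float = math.nan
    Pi1: float = math.nan
    Pi2: float = math.nan
    a_margin: float = math.nan
    b_margin: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def pi1_defined(self) -> bool:
        return math.isfinite(self.Pi1)

    @property
    def pi2_defined(self) -> bool:
        return math.isfinite(self.Pi2)


def classify_regime(params: ModelParameters, tol: float = REGIME_TOL) -> str:
    """Existence-regime label from the demand-competition inequalities.

    Returns one of ``coexistence``, ``bistable``, ``channel1-dominant``,
    ``channel2-dominant`` or ``degenerate`` (any inequality within ``tol``
    of its boundary).  The labels are mutually exclusive for m, n < 0.
    """
    d = params.interior_denominator          # r1*r2 - m*n
    s1 = params.r1 + params.m                # r1 - (-m)
    s2 = params.r2 + params.n                # r2 - (-n)
    if min(abs(d), abs(s1), abs(s2)) <= tol:
        return "degenerate"
    if d > 0 and s1 > 0 and s2 > 0:
        return "coexistence"
    if d < 0 and s1 < 0 and s2 < 0:
        return "bistable"
    if (d > 0 and s2 < 0) or (d < 0 and s1 > 0):
        return "channel1-dominant"
    if (d > 0 and s1 < 0) or (d < 0 and s2 > 0):
        return "channel2-dominant"
    return "degenerate"  # pragma: no cover - cases above are exhaustive


def reproduction_numbers(params: ModelParameters) -> tuple[float, float]:
    """Basic reproduction numbers (R1, R2) = (beta11*K1/gamma1, beta22*K2/gamma2)."""
    if params.gamma1 <= 0 or params.gamma2 <= 0:
        raise ParameterError("reproduction numbers require gamma1, gamma2 > 0")
    return (params.beta11 * params.K1 / params.gamma1,
            params.beta22 * params.K2 / params.gamma2)


_M_CONDITIONS = ("m<0, n<0 and ({r1*r2>m*n, r1>-m, r2>-n} "
                 "or {r1*r2<m*n, r1<-m, r2<-n})")


def demand_equilibria_2d(params: ModelParameters) -> list[EquilibriumPoint]:
    """Equilibria O, P, Q, M of the two-dimensional demand system.

    O, P, Q always exist.  M carries its closed-form coordinates and an
    existence verdict per the competition regime; a degenerate denominator
    (r1*r2 = m*n) is reported as nonexistence, not an exception.
    """
    validate_parameters(params).raise_for_errors()
    points = [
        EquilibriumPoint("O", np.zeros(2), True, condition_set="always"),
        EquilibriumPoint("P", np.array([params.K1, 0.0]), True, condition_set="always"),
        EquilibriumPoint("Q", np.array([0.0, params.K2]), True, condition_set="always"),
    ]
    d = params.interior_denominator
    regime = classify_regime(params)
    if abs(d) <= REGIME_TOL or regime == "degenerate":
        coords = np.full(2, np.nan)
        points.append(EquilibriumPoint(
            "M", coords, False, reason="degenerate (r1*r2 - m*n ~ 0 or boundary case)",
            condition_set=_M_CONDITIONS))
        return points
    coords = np.array([
        (params.m + params.r1) * params.r2 * params.K1 / d,
        (params.n + params.r2) * params.r1 * params.K2 / d,
    ])
    if not params.competitive:
        exists, reason = False, "m, n not both negative"
    elif regime in ("coexistence", "bistable"):
        exists, reason = True, None
    else:
        exists, reason = False, f"regime {regime}: interior point outside G"
    points.append(EquilibriumPoint("M", coords, exists, reason=reason,
                                   condition_set=_M_CONDITIONS))
    return points


def _get_M(params: ModelParameters,
           M: EquilibriumPoint | None = None) -> EquilibriumPoint:
    if M is None:
        M = demand_equilibria_2d(params)[3]
    return M


def boundary_infected_equilibria(
        params: ModelParameters) -> tuple[EquilibriumPoint, EquilibriumPoint]:
    """Boundary endemic equilibria P2 = (K1, I1E, 0, 0) and P4 = (0, 0, K2, I2E).

    I1E = K1*(1 - 1/R1) solves beta11*I1*(K1 - I1) - gamma1*I1 = 0; P2 exists
    iff R1 > 1 (at R1 = 1 it coincides with P1).  P4 is symmetric with
    I2E = K2*(1 - 1/R2).
    """
    R1, R2 = reproduction_numbers(params)
    I1E = params.K1 * (1.0 - 1.0 / R1) if R1 > 0 else 0.0
    I2E = params.K2 * (1.0 - 1.0 / R2) if R2 > 0 else 0.0
    P2 = EquilibriumPoint(
        "P2", np.array([params.K1, max(I1E, 0.0), 0.0, 0.0]), R1 > 1,
        reason=None if R1 > 1 else f"R1 = {R1:g} <= 1",
        condition_set="R1 = beta11*K1/gamma1 > 1")
    P4 = EquilibriumPoint(
        "P4", np.array([0.0, 0.0, params.K2, max(I2E, 0.0)]), R2 > 1,
        reason=None if R2 > 1 else f"R2 = {R2:g} <= 1",
        condition_set="R2 = beta22*K2/gamma2 > 1")
    return P2, P4


def interior_thresholds(params: ModelParameters,
                        M: EquilibriumPoint | None = None) -> ThresholdSet:
    """Threshold set (R1, R2, A, B, Pi1, Pi2) for the current parameters.

    A and B are computed from their defining expressions (not the identity
    A = gamma1, B = gamma2, which holds whenever M exists and serves as a
    self-check in the test suite).  Undefined Pi ratios (zero denominators)
    are flagged and reported as NaN rather than raised.
    """
    R1, R2 = reproduction_numbers(params)
    regime = classify_regime(params)
    ts = ThresholdSet(R1=R1, R2=R2, regime=regime)
    M = _get_M(params, M)
    if not M.exists:
        ts.flags.append(f"M does not exist ({M.reason}); A, B, Pi undefined")
        return ts
    N1E, N2E = M.coords
    ts.A = params.gamma1 - params.r1 * (1.0 - N1E / params.K1) - params.m * N2E / params.K2
    ts.B = params.gamma2 - params.r2 * (1.0 - N2E / params.K2) - params.n * N1E / params.K1
    ts.a_margin = ts.A - params.beta11 * N1E
    ts.b_margin = ts.B - params.beta22 * N2E
    if params.beta12 * N1E > 0:
        ts.Pi1 = ts.a_margin / (params.beta12 * N1E)
    else:
        ts.flags.append("Pi1 undefined (beta12*N1E = 0)")
    if ts.b_margin != 0:
        ts.Pi2 = params.beta21 * N2E / ts.b_margin
    else:
        ts.flags.append("Pi2 undefined (B = beta22*N2E)")
    return ts


def _largest_I1_root(I2: float, N1E: float, p: ModelParameters) -> float:
    """Largest root in [0, N1E] of (beta11*I1 + beta12*I2)(N1E - I1) = gamma1*I1.

    The left-minus-right expression is a concave quadratic in I1 that is
    nonnegative at I1 = 0 and negative at I1 = N1E, so the largest root is
    the relevant one; it is computed in closed form.
    """
    a = p.beta11
    b = a * N1E - p.beta12 * I2 - p.gamma1
    c = p.beta12 * I2 * N1E
    if a == 0:
        denom = p.beta12 * I2 + p.gamma1
        return min(c / denom, N1E) if denom > 0 else 0.0
    s = math.sqrt(max(b * b + 4.0 * a * c, 0.0))
    # two algebraically equal forms; pick the cancellation-free one
    root = (b + s) / (2.0 * a) if b >= 0 else 2.0 * c / (s - b)
    return float(np.clip(root, 0.0, N1E))


def interior_infected_equilibrium(
        params: ModelParameters,
        M: EquilibriumPoint | None = None) -> EquilibriumPoint:
    """The interior endemic equilibrium P6 = (N1E, I1EE, N2E, I2EE).

    At M the per-capita demand growth vanishes, so (I1EE, I2EE) solve::

        (beta11*I1 + beta12*I2)*(N1E - I1) = gamma1*I1
        (beta21*I1 + beta22*I2)*(N2E - I2) = gamma2*I2

    Solved by a deterministic 1D reduction: for each I2 the first equation
    has a unique relevant root I1*(I2) (closed form); the residual of the
    second equation along I1*(I2) is bracketed on (0, N2E) and solved by
    Brent iteration to 1e-12 relative.  When the channels decouple
    (beta12 = beta21 = 0) the two closed-form single-channel roots are used.
    No sign change means P6 does not exist (consistent with Pi1 >= Pi2).
    """
    M = _get_M(params, M)
    cond = "M exists, A - beta11*N1E > 0, B - beta22*N2E > 0, Pi1 < Pi2"
    if not M.exists:
        return EquilibriumPoint("P6", np.full(4, np.nan), False,
                                reason=f"M does not exist ({M.reason})",
                                condition_set=cond)
    N1E, N2E = M.coords
    p = params

    if p.beta12 == 0.0 and p.beta21 == 0.0:
        # decoupled channels: independent single-channel endemic levels
        I1EE = N1E - p.gamma1 / p.beta11 if p.beta11 > 0 else 0.0
        I2EE = N2E - p.gamma2 / p.beta22 if p.beta22 > 0 else 0.0
        if I1EE > 0 and I2EE > 0:
            return EquilibriumPoint("P6", np.array([N1E, I1EE, N2E, I2EE]),
                                    True, condition_set=cond)
        return EquilibriumPoint("P6", np.full(4, np.nan), False,
                                reason="decoupled channels below threshold",
                                condition_set=cond)

    def residual(I2: float) -> float:
        I1 = _largest_I1_root(I2, N1E, p)
        return ((p.beta21 * I1 + p.beta22 * I2) * (N2E - I2)
                - p.gamma2 * I2)

    lo = 1e-12 * N2E
    hi = N2E * (1.0 - 1e-12)
    bracket = None
    if residual(lo) > 0 and residual(hi) < 0:
        bracket = (lo, hi)
    else:
        grid = np.linspace(lo, hi, 512)
        vals = np.array([residual(x) for x in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)) < 0)[0]
        if sign_change.size:
            i = sign_change[0]
            bracket = (grid[i], grid[i + 1])
    if bracket is None:
        return EquilibriumPoint("P6", np.full(4, np.nan), False,
                                reason="no interior root (Pi1 >= Pi2)",
                                condition_set=cond)
    I2EE = brentq(residual, *bracket, xtol=1e-13 * max(1.0, N2E), rtol=1e-15)
    I1EE = _largest_I1_root(I2EE, N1E, p)
    if I1EE <= 0 or I2EE <= 0:
        return EquilibriumPoint("P6", np.full(4, np.nan), False,
                                reason="root on boundary", condition_set=cond)
    return EquilibriumPoint("P6", np.array([N1E, I1EE, N2E, I2EE]), True,
                            condition_set=cond)


def enumerate_equilibria_4d(params: ModelParameters) -> list[EquilibriumPoint]:
    """All seven equilibria P0..P6 of the four-dimensional system.

    P0, P1, P3 always exist; P2/P4 per the reproduction-number thresholds;
    P5 with M; P6 per :func:`interior_infected_equilibrium`.
    """
    validate_parameters(params).raise_for_errors()
    M = _get_M(params)
    P2, P4 = boundary_infected_equilibria(params)
    if M.exists:
        P5 = EquilibriumPoint("P5", np.array([M.coords[0], 0.0, M.coords[1], 0.0]),
                              True, condition_set=_M_CONDITIONS)
    else:
        P5 = EquilibriumPoint("P5", np.full(4, np.nan), False,
                              reason=M.reason, condition_set=_M_CONDITIONS)
    return [
        EquilibriumPoint("P0", np.zeros(4), True, condition_set="always"),
        EquilibriumPoint("P1", np.array([params.K1, 0.0, 0.0, 0.0]), True,
                         condition_set="always"),
        P2,
        EquilibriumPoint("P3", np.array([0.0, 0.0, params.K2, 0.0]), True,
                         condition_set="always"),
        P4,
        P5,
        interior_infected_equilibrium(params, M),
    ]


def equilibria_to_frame(points: list[EquilibriumPoint]) -> pd.DataFrame:
    """One row per equilibrium: label, coordinates, existence, condition."""
    rows = []
    for pt in points:
        row: dict[str, object] = {"label": pt.label, "exists": pt.exists,
                                  "reason": pt.reason or "",
                                  "condition_set": pt.condition_set}
        names = (["N1", "N2"] if pt.dim == 2 else ["N1", "I1", "N2", "I2"])
        row.update(dict(zip(names, pt.coords)))
        rows.append(row)
    return pd.DataFrame(rows)


def residual_norm(point: EquilibriumPoint, params: ModelParameters,
                  demographic_coupling: bool = True) -> float:
    """||rhs|| at the point's coordinates (2D or 4D system by dimension)."""
    if point.dim == 2:
        return float(np.linalg.norm(rhs_2d(point.coords, params)))
    return float(np.linalg.norm(
        rhs_4d(point.coords, params, demographic_coupling=demographic_coupling)))
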