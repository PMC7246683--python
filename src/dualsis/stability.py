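"""Jacobian-based stability classification and condition-table cross-validation.

Because the purchased-customer counts never feed back on the demand totals,
the 4x4 Jacobian is block lower-triangular in the ordering
((N1, N2), (I1, I2)): its spectrum is the union of the 2x2 demand block and
the 2x2 infection block.  This makes the eigenvalue verdicts below exactly
the union of the classic Lotka–Volterra competition analysis and the
next-generation analysis of the purchase-transmission subsystem.

The condition table maps threshold inequalities (regime set; R1, R2 versus
1; signs of A - beta11*N1E and B - beta22*N2E; Pi1 versus Pi2) to a claimed
attracting equilibrium and the state-space region (Omega1..Omega13) on which
attraction is claimed.  Claims on open regions are validated both by
eigenvalues and by trajectory convergence from sampled states inside the
region; claims on the separatrix (Omega12/13), a measure-zero set, are
validated by the eigenvalue structure — exactly one unstable direction,
transverse to the stable manifold on which attraction is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import Trajectory, detect_convergence, simulate, simulate_2d
from .equilibria import (EquilibriumPoint, classify_regime,
                         demand_equilibria_2d, enumerate_equilibria_4d,
                         interior_thresholds, reproduction_numbers)
from .model import jacobian_2d, jacobian_4d
from .parameters import ModelParameters

__all__ = [
    "StabilityReport",
    "ConditionRow",
    "ConditionTable",
    "classify_by_eigenvalues",
    "classify_by_conditions",
    "cross_validate",
    "CrossValidationSummary",
]


def _rate_scale(params: ModelParameters) -> float:
    return max(params.r1, params.r2, params.gamma1, params.gamma2)


@dataclass
class StabilityReport:
    """Eigenvalue-based stability verdict for one equilibrium."""

    point_label: str
    eigenvalues: np.ndarray        # sorted by real part, ascending
    verdict: str                   # asymptotically stable | unstable | saddle | nonhyperbolic
    tol: float
    n_unstable: int = 0            # eigenvalues with real part > tol

    @property
    def stable(self) -> bool:
        return self.verdict == "asymptotically stable"


def classify_by_eigenvalues(point: EquilibriumPoint, params: ModelParameters,
                            tol: float | None = None,
                            demographic_coupling: bool = True) -> StabilityReport:
    """Classify an equilibrium by the real parts of its Jacobian eigenvalues.

    ``tol`` defaults to 1e-8 times the largest rate (r1, r2, gamma1, gamma2);
    any eigenvalue with |Re| <= tol yields the verdict "nonhyperbolic".
    2D points (O, P, Q, M) are classified in the demand system, 4D points
    (P0..P6) in the full system.
    """
    if not point.exists:
        raise ValueError(f"{point.label} does not exist; nothing to classify")
    if tol is None:
        tol = 1e-8 * _rate_scale(params)
    if point.dim == 2:
        J = jacobian_2d(point.coords, params)
    else:
        J = jacobian_4d(point.coords, params, demographic_coupling)
    eig = np.linalg.eigvals(J)
    eig = eig[np.argsort(eig.real)]
    re = eig.real
    n_unstable = int(np.sum(re > tol))
    if np.any(np.abs(re) <= tol):
        verdict = "nonhyperbolic"
    elif np.all(re < -tol):
        verdict = "asymptotically stable"
    elif np.all(re > tol):
        verdict = "unstable"
    else:
        verdict = "saddle"
    return StabilityReport(point_label=point.label, eigenvalues=eig,
                           verdict=verdict, tol=tol, n_unstable=n_unstable)


@dataclass
class ConditionRow:
    """One fired row of the condition table."""

    point: str
    condition: str
    predicted: str                 # "asymptotically stable" or "unstable"
    omega: str                     # Omega1..Omega13
    on_separatrix: bool = False    # claim restricted to the stable manifold
    basin: str | None = None       # 'X' or 'Y' when the region is basin-restricted


@dataclass
class ConditionTable:
    """All condition rows fired by a parameter set, plus degeneracy flags."""

    regime: str
    R1: float
    R2: float
    rows: list[ConditionRow] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    @property
    def is_degenerate(self) -> bool:
        return bool(self.degenerate)


def classify_by_conditions(params: ModelParameters,
                           rel_tol: float = 1e-9) -> ConditionTable:
    """Evaluate every condition-table row's inequalities for this parameter set.

    Values within ``rel_tol`` (relative) of a condition boundary are recorded
    under ``degenerate`` and the affected rows are not fired.
    """
    regime = classify_regime(params)
    R1, R2 = reproduction_numbers(params)
    table = ConditionTable(regime=regime, R1=R1, R2=R2)
    table.rows.append(ConditionRow("P0", "always", "unstable", "Omega1"))
    if regime == "degenerate":
        table.degenerate.append("regime inequalities on a boundary")
        return table

    def near(x: float, boundary: float) -> bool:
        return abs(x - boundary) <= rel_tol * max(1.0, abs(x), abs(boundary))

    def r_rows(R: float, low: ConditionRow, high: ConditionRow) -> None:
        if near(R, 1.0):
            table.degenerate.append(f"{low.point}/{high.point}: R on threshold")
        elif R < 1.0:
            table.rows.append(low)
        else:
            table.rows.append(high)

    def pi_rows(low_omega: str, high_omega: str, sep: bool,
                basin: str | None) -> None:
        ts = interior_thresholds(params)
        if not (math.isfinite(ts.a_margin) and math.isfinite(ts.b_margin)):
            return
        if near(ts.a_margin, 0.0) or near(ts.b_margin, 0.0):
            table.degenerate.append("A - beta11*N1E or B - beta22*N2E on boundary")
            return
        if not (ts.a_margin > 0 and ts.b_margin > 0):
            return
        pi1 = ts.Pi1 if ts.pi1_defined else math.inf
        pi2 = ts.Pi2 if ts.pi2_defined else math.inf
        if math.isfinite(pi1) and math.isfinite(pi2) and near(pi1, pi2):
            table.degenerate.append("Pi1 ~ Pi2")
            return
        if pi1 > pi2:
            table.rows.append(ConditionRow(
                "P5", "A-b11*N1E>0, B-b22*N2E>0, Pi1>Pi2",
                "asymptotically stable", low_omega, on_separatrix=sep, basin=basin))
        else:
            table.rows.append(ConditionRow(
                "P6", "A-b11*N1E>0, B-b22*N2E>0, Pi1<Pi2",
                "asymptotically stable", high_omega, on_separatrix=sep, basin=basin))

    if regime == "bistable":
        r_rows(R1,
               ConditionRow("P1", "R1<1", "asymptotically stable", "Omega2", basin="Y"),
               ConditionRow("P2", "R1>1", "asymptotically stable", "Omega3", basin="Y"))
        r_rows(R2,
               ConditionRow("P3", "R2<1", "asymptotically stable", "Omega6", basin="X"),
               ConditionRow("P4", "R2>1", "asymptotically stable", "Omega7", basin="X"))
        pi_rows("Omega12", "Omega13", sep=True, basin=None)
    elif regime == "coexistence":
        pi_rows("Omega10", "Omega11", sep=False, basin=None)
    elif regime == "channel1-dominant":
        r_rows(R1,
               ConditionRow("P1", "R1<1", "asymptotically stable", "Omega4"),
               ConditionRow("P2", "R1>1", "asymptotically stable", "Omega5"))
    elif regime == "channel2-dominant":
        r_rows(R2,
               ConditionRow("P3", "R2<1", "asymptotically stable", "Omega8"),
               ConditionRow("P4", "R2>1", "asymptotically stable", "Omega9"))
    return table


# ---------------------------------------------------------------------------
# cross-validation of the condition table against eigenvalues + trajectories
# ---------------------------------------------------------------------------

@dataclass
class Disagreement:
    params: ModelParameters
    row: ConditionRow
    detail: str


@dataclass
class CrossValidationSummary:
    n_sets: int
    n_degenerate: int
    n_claims: int
    n_agree: int
    n_trajectory_checks: int
    disagreements: list[Disagreement] = field(default_factory=list)
    omegas_seen: set[str] = field(default_factory=set)

    @property
    def agreement_fraction(self) -> float:
        return self.n_agree / self.n_claims if self.n_claims else 1.0


def _basin_of(state2: np.ndarray, params: ModelParameters,
              points2d: list[EquilibriumPoint]) -> str:
    """Basin label of a demand state by forward simulation (the definition)."""
    p_point = next(pt for pt in points2d if pt.label == "P")
    q_point = next(pt for pt in points2d if pt.label == "Q")
    rate = min(params.r1, params.r2)
    t_end = 50.0 / rate
    state = np.asarray(state2, dtype=float)
    for _ in range(4):
        traj = simulate_2d(params, state, t_end, grid=50, rtol=1e-8, atol=1e-10)
        label = detect_convergence(traj, [p_point, q_point], tol=1e-4)
        if label == "P":
            return "Y"
        if label == "Q":
            return "X"
        state = traj.terminal_state
        t_end *= 4.0
    return "unresolved"


def _converges_to(params: ModelParameters, state0: np.ndarray,
                  target: EquilibriumPoint,
                  candidates: list[EquilibriumPoint],
                  demographic_coupling: bool = True) -> tuple[bool, str]:
    """Simulate from ``state0`` with a horizon adapted to the target's rates."""
    J = jacobian_4d(target.coords, params, demographic_coupling)
    rates = -np.linalg.eigvals(J).real
    rates = rates[rates > 0]
    slowest = rates.min() if rates.size else _rate_scale(params)
    t_end = min(30.0 / slowest, 5e6)
    state = np.asarray(state0, dtype=float)
    for _ in range(4):
        traj = simulate(params, state, t_end, grid=100, rtol=1e-9, atol=1e-11,
                        demographic_coupling=demographic_coupling)
        label = detect_convergence(traj, candidates, tol=1e-3)
        if label == target.label:
            return True, label
        if label != "none":
            return False, label
        state = traj.terminal_state
        t_end *= 5.0
    return False, "none"


def _initial_state_for_row(row: ConditionRow, params: ModelParameters,
                           points2d: list[EquilibriumPoint],
                           rng: np.random.Generator) -> np.ndarray | None:
    """A 4D state inside the row's Omega region (basin checked by simulation)."""
    K1, K2 = params.K1, params.K2
    if row.basin is None:
        N1, N2 = rng.uniform(0.2, 0.8) * K1, rng.uniform(0.2, 0.8) * K2
    else:
        # biased candidates near the claimed attractor, then random fallback
        if row.basin == "Y":
            cands = [(0.9 * K1, 0.05 * K2), (0.7 * K1, 0.1 * K2)]
        else:
            cands = [(0.05 * K1, 0.9 * K2), (0.1 * K2, 0.7 * K2)]
        cands += [(rng.uniform(0.05, 0.95) * K1, rng.uniform(0.05, 0.95) * K2)
                  for _ in range(12)]
        found = None
        for N1, N2 in cands:
            if _basin_of(np.array([N1, N2]), params, points2d) == row.basin:
                found = (N1, N2)
                break
        if found is None:
            return None
        N1, N2 = found
    I1 = 0.5 * N1
    I2 = 0.5 * N2
    return np.array([N1, I1, N2, I2])


def cross_validate(n_samples: int = 200, seed: int = 0,
                   regimes: Sequence[str] = ("coexistence", "bistable",
                                             "channel1-dominant",
                                             "channel2-dominant"),
                   check_trajectories: bool = True,
                   demographic_coupling: bool = True) -> CrossValidationSummary:
    """Compare condition-table verdicts with eigenvalue (and trajectory) verdicts.

    Samples ``n_samples`` parameter sets split across the competition
    regimes, fires the condition table for each, and checks every fired row:

    * "unstable" claims: the eigenvalue verdict must be unstable or saddle;
    * open-region stable claims: all eigenvalues in the left half plane,
      and (when ``check_trajectories``) a sampled state inside the claimed
      region converges to the claimed point;
    * separatrix-restricted claims (Omega12/13): exactly one unstable
      eigendirection (the one transverse to the stable manifold).

    Nonhyperbolic verdicts and condition-boundary parameter sets are
    excluded as degenerate.  Any disagreement is reported with the full
    parameter set.
    """
    from .scenarios import sample_parameters  # deferred: scenarios builds on dynamics

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    per = [n_samples // len(regimes)] * len(regimes)
    for i in range(n_samples - sum(per)):
        per[i] += 1
    summary = CrossValidationSummary(n_sets=0, n_degenerate=0, n_claims=0,
                                     n_agree=0, n_trajectory_checks=0)
    for regime, count in zip(regimes, per):
        if count == 0:
            continue
        for params in sample_parameters(regime, count, seed=int(rng.integers(2**31))):
            summary.n_sets += 1
            table = classify_by_conditions(params)
            if table.is_degenerate:
                summary.n_degenerate += 1
                continue
            points = {pt.label: pt for pt in enumerate_equilibria_4d(params)}
            points2d = demand_equilibria_2d(params)
            candidates = [pt for pt in points.values() if pt.exists]
            for row in table.rows:
                point = points[row.point]
                if not point.exists:
                    summary.n_claims += 1
                    summary.disagreements.append(Disagreement(
                        params, row, "table fires but point does not exist"))
                    continue
                rep = classify_by_eigenvalues(point, params,
                                              demographic_coupling=demographic_coupling)
                if rep.verdict == "nonhyperbolic":
                    summary.n_degenerate += 1
                    continue
                summary.n_claims += 1
                summary.omegas_seen.add(row.omega)
                if row.predicted == "unstable":
                    ok = rep.verdict in ("unstable", "saddle")
                    detail = "" if ok else f"eigen verdict {rep.verdict}"
                elif row.on_separatrix:
                    ok = rep.verdict == "saddle" and rep.n_unstable == 1
                    detail = ("" if ok else
                              f"expected 1D-unstable saddle, got {rep.verdict} "
                              f"with {rep.n_unstable} unstable directions")
                else:
                    ok = rep.verdict == "asymptotically stable"
                    detail = "" if ok else f"eigen verdict {rep.verdict}"
                    if ok and check_trajectories:
                        state0 = _initial_state_for_row(row, params, points2d, rng)
                        if state0 is not None:
                            summary.n_trajectory_checks += 1
                            converged, got = _converges_to(
                                params, state0, point, candidates,
                                demographic_coupling)
                            if not converged:
                                ok = False
                                detail = (f"trajectory from {row.omega} reached "
                                          f"{got!r}, claimed {row.point}")
                if ok:
                    summary.n_agree += 1
                else:
                    summary.disagreements.append(Disagreement(params, row, detail))
    return summary
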