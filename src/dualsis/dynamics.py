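"""Numerical integration, convergence detection and phase-plane analysis.

Trajectories are computed with SciPy's adaptive LSODA integrator (stiff/
non-stiff switching) at tight default tolerances (rtol 1e-9, atol 1e-12),
with dense output on a uniform grid.  Phase-plane structures — nullclines,
the saddle separatrix of the bistable demand regime, and the basin partition
X/Y it induces — are computed in the two-dimensional N-projection, which is
autonomous (the purchased-customer counts never feed back on demand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from shapely.geometry import LineString, Point, Polygon

from .model import (ABS_TOL, REL_TOL, in_region, jacobian_2d, rhs_2d, rhs_4d,
                    sis_rhs_single)
from .parameters import ModelParameters, SingleChannelParameters
from .equilibria import EquilibriumPoint, demand_equilibria_2d

__all__ = [
    "Trajectory",
    "BasinPartition",
    "simulate",
    "simulate_2d",
    "simulate_single",
    "total_sales_series",
    "detect_convergence",
    "nullclines_2d",
    "separatrix_2d",
    "omega_region_membership",
    "OMEGA_LABELS",
]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """Time-indexed states from numerical integration.

    ``states`` has one row per output time; columns are (N1, I1, N2, I2) for
    the 4D system, (N1, N2) for the 2D demand system, (S, I) for the single
    channel.  ``left_region`` flags excursions beyond the admissible box by
    more than the clipping tolerance (1e-6 relative); smaller excursions are
    clipped silently.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters | SingleChannelParameters
    rtol: float
    atol: float
    demographic_coupling: bool = True
    nfev: int = 0
    left_region: bool = False
    columns: tuple[str, ...] = ("N1", "I1", "N2", "I2")

    @property
    def dim(self) -> int:
        return self.states.shape[1]

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(self.columns))
        frame.insert(0, "t", self.times)
        if self.dim == 4:
            frame["total_sales"] = frame["I1"] + frame["I2"]
        return frame


def _integrate(fun, state0, t_end, grid, rtol, atol, method):
    t_eval = np.linspace(0.0, t_end, grid)
    sol = solve_ivp(fun, (0.0, t_end), np.asarray(state0, dtype=float),
                    method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise IntegrationError(f"integration failed: {sol.message}", last)
    return sol


def simulate(params: ModelParameters, state0: Sequence[float], t_end: float,
             *, grid: int = 1000, rtol: float = 1e-9, atol: float = 1e-12,
             demographic_coupling: bool = True,
             method: str = "LSODA") -> Trajectory:
    """Integrate the four-dimensional system from ``state0`` over [0, t_end].

    ``state0`` must lie in G'; states that exit G' by more than 1e-6
    relative are flagged (``left_region``), smaller excursions clipped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not in_region(state0, params, tol=1e-6):
        raise ValueError(f"initial state {state0} outside region G'")
    sol = _integrate(lambda t, y: rhs_4d(y, params, demographic_coupling),
                     state0, t_end, grid, rtol, atol, method)
    states = sol.y.T.copy()
    left = False
    clip_tol = 1e-6
    for i, y in enumerate(states):
        if not in_region(y, params, tol=clip_tol):
            left = True
        K1, K2 = params.K1, params.K2
        N1 = min(max(y[0], 0.0), K1)
        N2 = min(max(y[2], 0.0), K2)
        states[i] = (N1, min(max(y[1], 0.0), N1), N2, min(max(y[3], 0.0), N2))
    return Trajectory(times=sol.t, states=states, params=params, rtol=rtol,
                      atol=atol, demographic_coupling=demographic_coupling,
                      nfev=sol.nfev, left_region=left)


def simulate_2d(params: ModelParameters, state0: Sequence[float], t_end: float,
                *, grid: int = 1000, rtol: float = 1e-9, atol: float = 1e-12,
                method: str = "LSODA") -> Trajectory:
    """Integrate the two-dimensional demand system (N1, N2)."""
    sol = _integrate(lambda t, y: rhs_2d(y, params), state0, t_end, grid,
                     rtol, atol, method)
    return Trajectory(times=sol.t, states=sol.y.T.copy(), params=params,
                      rtol=rtol, atol=atol, nfev=sol.nfev,
                      columns=("N1", "N2"))


def simulate_single(params: SingleChannelParameters, I0: float, t_end: float,
                    *, grid: int = 1000, rtol: float = 1e-9,
                    atol: float = 1e-12) -> Trajectory:
    """Integrate the single-channel SIS model from (S, I) = (N - I0, I0)."""
    state0 = (params.N - I0, I0)
    sol = _integrate(lambda t, y: sis_rhs_single(y, params), state0, t_end,
                     grid, rtol, atol, "LSODA")
    return Trajectory(times=sol.t, states=sol.y.T.copy(), params=params,
                      rtol=rtol, atol=atol, nfev=sol.nfev, columns=("S", "I"))


def total_sales_series(traj: Trajectory) -> pd.Series:
    """Total purchased customers I1 + I2 over time (persons)."""
    if traj.dim != 4:
        raise ValueError("total sales are defined for 4D trajectories")
    return pd.Series(traj.states[:, 1] + traj.states[:, 3], index=traj.times,
                     name="total_sales")


def detect_convergence(traj: Trajectory,
                       candidates: Sequence[EquilibriumPoint],
                       tol: float = 1e-3) -> str:
    """Label of the equilibrium the trajectory has settled at, or "none".

    A candidate matches when every state over the final 10% of the horizon
    is within ``tol`` relative (scaled by max(1, ||coords||)) of its
    coordinates.
    """
    window = traj.states[traj.times >= traj.times[-1] * 0.9]
    for cand in candidates:
        if not cand.exists or len(cand.coords) != traj.dim:
            continue
        scale = max(1.0, float(np.linalg.norm(cand.coords)))
        if np.all(np.linalg.norm(window - cand.coords, axis=1) <= tol * scale):
            return cand.label
    return "none"


def nullclines_2d(params: ModelParameters, grid: int = 200) -> dict[str, np.ndarray]:
    """Nullcline curves of the demand system on G.

    The trivial nullclines are the axes; the interior ones are the straight
    lines r1*(1 - N1/K1) + m*N2/K2 = 0 and r2*(1 - N2/K2) + n*N1/K1 = 0.
    Their intersection, when inside G, is the interior equilibrium M.
    """
    if grid < 2:
        raise ValueError("grid resolution must be >= 2")
    p = params
    out: dict[str, np.ndarray] = {
        "N1_axis": np.column_stack([np.zeros(grid), np.linspace(0, p.K2, grid)]),
        "N2_axis": np.column_stack([np.linspace(0, p.K1, grid), np.zeros(grid)]),
    }
    N1 = np.linspace(0.0, p.K1, grid)
    if p.m != 0:
        # g1 = 0  =>  N2 = -(r1/m)*(1 - N1/K1)*K2
        N2 = -(p.r1 / p.m) * (1.0 - N1 / p.K1) * p.K2
        out["N1_nullcline"] = np.column_stack([N1, N2])
    else:
        out["N1_nullcline"] = np.column_stack(
            [np.full(grid, p.K1), np.linspace(0, p.K2, grid)])
    N2 = np.linspace(0.0, p.K2, grid)
    if p.n != 0:
        N1_line = -(p.r2 / p.n) * (1.0 - N2 / p.K2) * p.K1
        out["N2_nullcline"] = np.column_stack([N1_line, N2])
    else:
        out["N2_nullcline"] = np.column_stack(
            [np.linspace(0, p.K1, grid), np.full(grid, p.K2)])
    return out


@dataclass
class BasinPartition:
    """Saddle separatrix of the bistable demand regime and the basins it cuts.

    The stable manifold of the saddle M consists of two branches: one from
    the origin O up to M, the other from M out to the upper boundary of G.
    Together they divide G into basin Y (containing the channel-1 attractor
    P = (K1, 0)) and basin X (containing Q = (0, K2)).
    """

    M: np.ndarray
    branch_lower: np.ndarray          # polyline O -> M
    branch_upper: np.ndarray          # polyline M -> boundary exit S
    params: ModelParameters
    curve_tol: float = 0.0            # on-curve distance threshold
    _curve: LineString = field(init=False, repr=False)
    _polygon_Y: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.vstack([self.branch_lower, self.branch_upper[1:]])
        self._curve = LineString(pts)
        if self.curve_tol == 0.0:
            self.curve_tol = 1e-6 * max(self.params.K1, self.params.K2)
        # close the Y region through the lower-right boundary of G
        exit_pt = self.branch_upper[-1]
        boundary: list[tuple[float, float]] = []
        K1, K2 = self.params.K1, self.params.K2
        if exit_pt[1] >= K2 - self.curve_tol and exit_pt[0] < K1 - self.curve_tol:
            boundary.append((K1, K2))   # exited through the top edge
        boundary.append((K1, 0.0))
        poly = Polygon(np.vstack([pts, boundary]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        self._polygon_Y = poly

    def distance_to_curve(self, point: Sequence[float]) -> float:
        return float(self._curve.distance(Point(point)))

    def on_curve(self, point: Sequence[float]) -> bool:
        return self.distance_to_curve(point) <= self.curve_tol

    def classify(self, point: Sequence[float]) -> str:
        """'Y' (basin of P), 'X' (basin of Q) or 'on-curve'."""
        if self.on_curve(point):
            return "on-curve"
        return "Y" if self._polygon_Y.contains(Point(point)) else "X"


def separatrix_2d(params: ModelParameters,
                  M: EquilibriumPoint | None = None,
                  eps: float = 1e-4,
                  t_back: float | None = None) -> BasinPartition:
    """Stable-manifold separatrix through the demand saddle M.

    Requires the bistable regime (r1*r2 < m*n, r1 < -m, r2 < -n), in which M
    is a saddle of the 2D demand system.  Both branches are traced by
    integrating the demand flow backward in time from M +/- eps*v_stable,
    stopping at the boundary of G (slightly enlarged) or after a horizon
    long enough for the origin branch to collapse onto O.
    """
    if M is None:
        M = demand_equilibria_2d(params)[3]
    if not M.exists:
        raise ValueError(f"M does not exist: {M.reason}")
    J = jacobian_2d(M.coords, params)
    eigvals, eigvecs = np.linalg.eig(J)
    if not (eigvals.real.min() < 0 < eigvals.real.max()):
        raise ValueError(
            "M is not a saddle of the demand system; the separatrix is only "
            "defined in the bistable regime (r1*r2 < m*n, r1 < -m, r2 < -n)")
    v = eigvecs[:, np.argmin(eigvals.real)].real
    v = v / np.linalg.norm(v)
    scale = max(params.K1, params.K2)
    if t_back is None:
        t_back = 80.0 / min(params.r1, params.r2)

    slack = 1e-9 * scale

    def backward(t, y):
        return -rhs_2d(y, params)

    def hit_boundary(t, y):
        return min(y[0] + slack, y[1] + slack,
                   1.05 * params.K1 - y[0], 1.05 * params.K2 - y[1])
    hit_boundary.terminal = True  # type: ignore[attr-defined]

    branches = []
    for sign in (+1.0, -1.0):
        seed = M.coords + sign * eps * scale * v
        sol = solve_ivp(backward, (0.0, t_back), seed, method="LSODA",
                        rtol=1e-10, atol=1e-12 * scale, events=hit_boundary,
                        dense_output=True, max_step=t_back / 200.0)
        pts = sol.y.T
        pts = np.clip(pts, 0.0, [params.K1, params.K2])
        branches.append(pts)

    # orient: the lower branch ends near O, the upper one away from it
    end_norms = [np.linalg.norm(b[-1]) for b in branches]
    lower = branches[int(np.argmin(end_norms))]
    upper = branches[int(np.argmax(end_norms))]
    if np.linalg.norm(lower[-1]) < 1e-3 * scale:
        lower[-1] = (0.0, 0.0)  # snap onto the origin
    # store polylines running O -> M and M -> exit
    branch_lower = np.vstack([lower[::-1], M.coords])
    branch_upper = np.vstack([M.coords, upper])
    return BasinPartition(M=M.coords.copy(), branch_lower=branch_lower,
                          branch_upper=branch_upper, params=params)


#: The thirteen state-space regions on which asymptotic stability is claimed.
OMEGA_LABELS = tuple(f"Omega{i}" for i in range(1, 14))

_BASIN_DEPENDENT = {"Omega2", "Omega3", "Omega6", "Omega7", "Omega12", "Omega13"}


def omega_region_membership(state: Sequence[float], params: ModelParameters,
                            partition: BasinPartition | None = None,
                            labels: Sequence[str] | None = None) -> list[str]:
    """All Omega-region labels satisfied by a 4D state.

    Omega1 is the whole admissible box G'; the others add nonzero-coordinate
    conditions ("!= 0" tested as > 1e-9 * max(K1, K2)) and, for
    Omega2/3/6/7/12/13, membership of the N-projection in basin Y, basin X,
    or the separatrix itself — these require ``partition``.
    """
    if labels is None:
        labels = OMEGA_LABELS
    requested = set(labels)
    if requested & _BASIN_DEPENDENT and partition is None:
        raise ValueError(
            f"labels {sorted(requested & _BASIN_DEPENDENT)} reference the "
            "basin partition; pass the result of separatrix_2d()")
    N1, I1, N2, I2 = np.asarray(state, dtype=float)
    nz_tol = 1e-9 * max(params.K1, params.K2)
    nz = {"N1": N1 > nz_tol, "I1": I1 > nz_tol,
          "N2": N2 > nz_tol, "I2": I2 > nz_tol}
    in_gp = in_region(state, params, tol=REL_TOL)
    basin = partition.classify((N1, N2)) if partition is not None else None
    defs = {
        "Omega1": in_gp,
        "Omega2": in_gp and basin == "Y",
        "Omega3": in_gp and basin == "Y" and nz["I1"],
        "Omega4": in_gp and nz["N1"],
        "Omega5": in_gp and nz["N1"] and nz["I1"],
        "Omega6": in_gp and basin == "X",
        "Omega7": in_gp and basin == "X" and nz["I2"],
        "Omega8": in_gp and nz["N2"],
        "Omega9": in_gp and nz["N2"] and nz["I2"],
        "Omega10": in_gp and nz["N1"] and nz["N2"],
        "Omega11": in_gp and all(nz.values()),
        "Omega12": in_gp and basin == "on-curve",
        "Omega13": in_gp and basin == "on-curve" and nz["I1"] and nz["I2"],
    }
    return [lab for lab in OMEGA_LABELS if lab in requested and defs[lab]]
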