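"""Transmission-rate sweep scenarios and the seeded parameter sampler.

Three scenarios ship with the package (YAML configs under ``configs/``):

* ``s51`` — bistable demand regime (m = -1.2, n = -1.5), sweep of the
  offline within-channel rate beta11 across the single-channel threshold
  R1 = beta11*K1/gamma1 = 1, horizon t = 300;
* ``s52`` — channel-2-dominant regime (m = -1.2, n = -0.5), sweep of the
  online within-channel rate beta22, horizon t = 10;
* ``s53`` — coexistence regime (m = -0.8, n = -0.5), joint sweep of the
  cross-channel rates (beta12, beta21) across the Pi1 < Pi2 invasion
  threshold, horizon t = 10.

All use K1 = K2 = 1000, N1(0) = N2(0) = 100 and one seed purchaser per
channel (I1(0) = I2(0) = 1); an SIS system started at I = 0 stays there, so
a nonzero seed is required for sales to develop at all.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory, detect_convergence, simulate, total_sales_series
from .equilibria import classify_regime, enumerate_equilibria_4d, reproduction_numbers
from .parameters import ModelParameters, ParameterError, validate_parameters

__all__ = [
    "ScenarioConfig",
    "SweepResult",
    "MonotonicityVerdict",
    "builtin_scenario",
    "load_scenario",
    "run_sweep",
    "monotonicity_check",
    "sample_parameters",
    "render_outputs",
    "BUILTIN_SCENARIOS",
]

BUILTIN_SCENARIOS = ("s51", "s52", "s53")


@dataclass
class ScenarioConfig:
    """A base parameter set plus one or more parallel sweep value lists."""

    scenario_id: str
    params: ModelParameters
    sweep: dict[str, list[float]]
    state0: np.ndarray
    t_end: float
    seed: int = 0
    demographic_coupling: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.sweep.values()}
        if len(lengths) != 1:
            raise ParameterError("sweep value lists must have equal length")
        for name, values in self.sweep.items():
            if any(b >= a for a, b in zip(values[1:], values)):
                raise ParameterError(f"sweep values for {name} must be strictly increasing")

    @property
    def n_runs(self) -> int:
        return len(next(iter(self.sweep.values())))

    def parameter_sets(self) -> list[ModelParameters]:
        sets = []
        for i in range(self.n_runs):
            changes = {name: values[i] for name, values in self.sweep.items()}
            params = self.params.replace(**changes)
            validate_parameters(params).raise_for_errors()
            sets.append(params)
        return sets


def _scenario_from_mapping(data: dict, scenario_id: str) -> ScenarioConfig:
    params = ModelParameters.from_dict(data)
    sweep = {k: [float(x) for x in v] for k, v in data.get("sweep", {}).items()}
    state0 = np.array([float(data.get(k, d)) for k, d in
                       (("N1_0", 100.0), ("I1_0", 1.0), ("N2_0", 100.0), ("I2_0", 1.0))])
    return ScenarioConfig(
        scenario_id=scenario_id, params=params, sweep=sweep, state0=state0,
        t_end=float(data.get("t_end", 100.0)),
        demographic_coupling=bool(data.get("demographic_coupling", True)),
        notes=str(data.get("notes", "")))


def builtin_scenario(name: str) -> ScenarioConfig:
    """Load one of the shipped scenario configs (s51, s52, s53)."""
    if name not in BUILTIN_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {BUILTIN_SCENARIOS}")
    ref = importlib.resources.files("dualsis") / "configs" / f"{name}.yaml"
    data = yaml.safe_load(ref.read_text())
    return _scenario_from_mapping(data, name)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a custom sweep scenario from a YAML/JSON config file."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return _scenario_from_mapping(data, data.get("scenario_id", path.stem))


@dataclass
class SweepResult:
    config: ScenarioConfig
    trajectories: list[Trajectory]
    summary: pd.DataFrame


def run_sweep(config: ScenarioConfig, *, grid: int = 1000,
              rtol: float = 1e-9, atol: float = 1e-12) -> SweepResult:
    """One simulation per sweep value, with a per-run summary table.

    Summary columns: the sweep variable values, R1, R2, terminal channel and
    total sales, and the equilibrium (if any) the run has settled at by the
    horizon.  All parameter sets are validated before any run starts.
    """
    param_sets = config.parameter_sets()
    trajectories = []
    rows = []
    for i, params in enumerate(param_sets):
        traj = simulate(params, config.state0, config.t_end, grid=grid,
                        rtol=rtol, atol=atol,
                        demographic_coupling=config.demographic_coupling)
        trajectories.append(traj)
        R1, R2 = reproduction_numbers(params)
        candidates = [pt for pt in enumerate_equilibria_4d(params) if pt.exists]
        terminal = traj.terminal_state
        row = {name: values[i] for name, values in config.sweep.items()}
        row.update({
            "R1": R1, "R2": R2,
            "terminal_N1": terminal[0], "terminal_I1": terminal[1],
            "terminal_N2": terminal[2], "terminal_I2": terminal[3],
            "terminal_total_sales": terminal[1] + terminal[3],
            "matched_equilibrium": detect_convergence(traj, candidates),
        })
        rows.append(row)
    return SweepResult(config=config, trajectories=trajectories,
                       summary=pd.DataFrame(rows))


@dataclass
class MonotonicityVerdict:
    nondecreasing: bool
    strictly_increasing: bool
    values: list[float]

    def __bool__(self) -> bool:
        return self.nondecreasing


def monotonicity_check(summary: pd.DataFrame,
                       column: str = "terminal_total_sales",
                       rel_tol: float = 1e-9) -> MonotonicityVerdict:
    """Is the terminal quantity nondecreasing along the sweep?

    ``rel_tol`` absorbs solver noise on ties; a flat (all-tied) sweep is
    nondecreasing but not strictly increasing.
    """
    values = summary[column].tolist()
    if len(values) < 2:
        raise ValueError("monotonicity requires at least two sweep values")
    scale = max(1.0, max(abs(v) for v in values))
    diffs = np.diff(values)
    return MonotonicityVerdict(
        nondecreasing=bool(np.all(diffs >= -rel_tol * scale)),
        strictly_increasing=bool(np.all(diffs > rel_tol * scale)),
        values=values)


# ---------------------------------------------------------------------------
# seeded parameter sampler
# ---------------------------------------------------------------------------

_REGIMES = ("coexistence", "bistable", "channel1-dominant", "channel2-dominant")

#: Margin with which every strict regime inequality must hold.
SAMPLER_MARGIN = 1e-3


def sample_parameters(regime: str, n: int, seed: int = 0,
                      margin: float = SAMPLER_MARGIN,
                      max_draws: int = 200_000) -> list[ModelParameters]:
    """Rejection-sample ``n`` parameter sets from one competition regime.

    Draws r ~ U(0.5, 2), K ~ U(500, 2000), m, n ~ U(-2, -0.05),
    beta ~ log-U(1e-6, 1e-1), gamma ~ U(0.005, 0.1), keeping sets whose
    regime inequalities hold with at least ``margin``.  Deterministic for a
    fixed seed.
    """
    if regime not in _REGIMES:
        raise ValueError(f"regime must be one of {_REGIMES}, got {regime!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[ModelParameters] = []
    draws = 0
    while len(out) < n:
        draws += 1
        if draws > max_draws:
            raise RuntimeError(
                f"rejection budget exhausted after {max_draws} draws for {regime}")
        r1, r2 = rng.uniform(0.5, 2.0, size=2)
        K1, K2 = rng.uniform(500.0, 2000.0, size=2)
        m, nn = rng.uniform(-2.0, -0.05, size=2)
        betas = 10.0 ** rng.uniform(-6.0, -1.0, size=4)
        g1, g2 = rng.uniform(0.005, 0.1, size=2)
        d = r1 * r2 - m * nn
        s1 = r1 + m
        s2 = r2 + nn
        if regime == "coexistence":
            ok = d > margin and s1 > margin and s2 > margin
        elif regime == "bistable":
            ok = d < -margin and s1 < -margin and s2 < -margin
        elif regime == "channel1-dominant":
            ok = (d > margin and s2 < -margin) or (d < -margin and s1 > margin)
        else:
            ok = (d > margin and s1 < -margin) or (d < -margin and s2 > margin)
        if not ok:
            continue
        out.append(ModelParameters(
            r1=r1, r2=r2, K1=K1, K2=K2, m=m, n=nn,
            beta11=betas[0], beta12=betas[1], beta21=betas[2], beta22=betas[3],
            gamma1=g1, gamma2=g2))
    return out


# ---------------------------------------------------------------------------
# figure/table rendering
# ---------------------------------------------------------------------------

def render_outputs(result: SweepResult, outdir: str | Path) -> list[Path]:
    """Write the summary CSV and a total-sales-versus-time figure.

    One PNG per sweep, all runs overlaid with a legend keyed by the sweep
    values.  Returns the written paths; an empty result writes nothing.
    """
    if not result.trajectories:
        print("render_outputs: empty sweep result, nothing written")
        return []
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.config.scenario_id
    written = []

    csv_path = outdir / f"{sid}_summary.csv"
    result.summary.to_csv(csv_path, index=False)
    written.append(csv_path)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    sweep_names = list(result.config.sweep)
    for i, traj in enumerate(result.trajectories):
        sales = total_sales_series(traj)
        label = ", ".join(f"{nm}={result.config.sweep[nm][i]:g}" for nm in sweep_names)
        ax.plot(sales.index, sales.values, label=label)
    ax.set_xlabel("time t")
    ax.set_ylabel("total sales I1 + I2 (persons)")
    ax.set_title(f"Scenario {sid}: total dual-channel sales")
    ax.legend(fontsize=8)
    fig.tight_layout()
    png_path = outdir / f"{sid}_total_sales.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    written.append(png_path)
    return written
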