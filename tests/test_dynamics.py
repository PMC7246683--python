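"""Integration, convergence detection, phase-plane structures, Omega regions."""

import numpy as np
import pytest

from dualsis import (ModelParameters, SingleChannelParameters,
                     classify_by_conditions, demand_equilibria_2d,
                     detect_convergence, enumerate_equilibria_4d,
                     nullclines_2d, omega_region_membership, separatrix_2d,
                     simulate, simulate_2d, simulate_single,
                     total_sales_series)
from dualsis.dynamics import BasinPartition
from dualsis.stability import _basin_of, _converges_to
from dualsis.scenarios import builtin_scenario, sample_parameters


@pytest.fixture
def partition(s51_params) -> BasinPartition:
    return separatrix_2d(s51_params)


class TestSimulate:
    def test_equilibrium_start_stays_put(self, s51_params):
        state0 = (s51_params.K1, 0.0, 0.0, 0.0)  # P1 exactly
        traj = simulate(s51_params, state0, 50.0, grid=100)
        assert np.allclose(traj.states, state0, atol=1e-9)

    def test_supra_threshold_run_reaches_endemic_point(self, s51_params):
        params = s51_params.replace(beta11=0.00009)  # R1 = 9
        traj = simulate(params, (100, 1, 100, 1), 300.0)
        cands = [pt for pt in enumerate_equilibria_4d(params) if pt.exists]
        assert detect_convergence(traj, cands) == "P2"
        I1E = params.K1 * (1 - 1 / 9)
        assert traj.terminal_state[1] == pytest.approx(I1E, rel=1e-2)

    def test_short_horizon_matches_nothing(self, s51_params):
        params = s51_params.replace(beta11=0.00009)
        traj = simulate(params, (100, 1, 100, 1), 5.0)
        cands = [pt for pt in enumerate_equilibria_4d(params) if pt.exists]
        assert detect_convergence(traj, cands) == "none"

    def test_initial_state_outside_box_rejected(self, s51_params):
        with pytest.raises(ValueError):
            simulate(s51_params, (2 * s51_params.K1, 0, 0, 0), 10.0)
        with pytest.raises(ValueError):
            simulate(s51_params, (100, 1, 100, 1), -1.0)

    def test_solver_tolerance_robustness(self):
        """Halving integrator tolerances barely moves the terminal state."""
        for name in ("s51", "s52", "s53"):
            cfg = builtin_scenario(name)
            params = cfg.parameter_sets()[0]
            a = simulate(params, cfg.state0, cfg.t_end, rtol=1e-9, atol=1e-12)
            b = simulate(params, cfg.state0, cfg.t_end, rtol=5e-10, atol=5e-13)
            scale = np.maximum(1.0, np.abs(a.terminal_state))
            assert np.all(np.abs(a.terminal_state - b.terminal_state) / scale < 1e-5)


class TestSingleChannelConservation:
    @pytest.mark.parametrize("beta,gamma,N", [
        (0.0005, 0.1, 1000.0),   # R0 = 5, endemic
        (0.00005, 0.1, 1000.0),  # R0 = 0.5, fade-out
    ])
    def test_total_population_conserved(self, beta, gamma, N):
        params = SingleChannelParameters(beta=beta, gamma=gamma, N=N)
        traj = simulate_single(params, I0=1.0, t_end=300.0)
        total = traj.states.sum(axis=1)
        assert np.max(np.abs(total - N)) < 1e-6 * N

    def test_reduction_inside_full_model(self, s51_params):
        """With channel 2 empty and no cross transmission, the full model
        runs the single-channel system on N1 pinned at K1."""
        params = s51_params.replace(beta11=0.00003, beta12=0.0, beta21=0.0)
        traj = simulate(params, (params.K1, 1.0, 0.0, 0.0), 2000.0)
        assert np.allclose(traj.states[:, 0], params.K1, rtol=1e-9)
        assert np.allclose(traj.states[:, 2:], 0.0, atol=1e-9)
        # I1 converges to the endemic level K1*(1 - 1/R1)
        assert traj.terminal_state[1] == pytest.approx(
            params.K1 * (1 - 1 / 3), rel=1e-6)


class TestTotalSales:
    def test_no_purchasers_no_sales(self, s53_params):
        traj = simulate(s53_params, (100, 0, 100, 0), 50.0, grid=100)
        assert np.all(total_sales_series(traj).values == 0.0)

    def test_constant_at_interior_endemic_point(self, s53_params):
        P6 = next(pt for pt in enumerate_equilibria_4d(s53_params)
                  if pt.label == "P6")
        traj = simulate(s53_params, P6.coords, 100.0, grid=100)
        sales = total_sales_series(traj)
        assert np.allclose(sales.values, P6.coords[1] + P6.coords[3], rtol=1e-7)

    def test_nonnegative_along_any_admissible_trajectory(self, s52_params):
        traj = simulate(s52_params, (100, 1, 100, 1), 50.0, grid=100)
        assert np.all(total_sales_series(traj).values >= 0.0)


class TestNullclines:
    def test_uncoupled_channel_one_line_is_vertical(self, s51_params):
        curves = nullclines_2d(s51_params.replace(m=0.0))
        assert np.allclose(curves["N1_nullcline"][:, 0], s51_params.K1)

    def test_interior_intersection_is_M(self, s51_params):
        curves = nullclines_2d(s51_params, grid=500)
        line = curves["N1_nullcline"]
        N2_at_250 = np.interp(250.0, line[:, 0], line[:, 1])
        assert N2_at_250 == pytest.approx(625.0, rel=1e-9)
        line2 = curves["N2_nullcline"]
        order = np.argsort(line2[:, 0])
        N2_at_250_b = np.interp(250.0, line2[order, 0], line2[order, 1])
        assert N2_at_250_b == pytest.approx(625.0, rel=1e-9)

    def test_channel_dominant_intersection_leaves_G(self, s52_params):
        """When the line intersection falls outside G, M is nonexistent."""
        p = s52_params
        A = np.array([[p.r1 / p.K1, -p.m / p.K2], [-p.n / p.K1, p.r2 / p.K2]])
        inter = np.linalg.solve(A, [p.r1, p.r2])
        M = demand_equilibria_2d(p)[3]
        assert not M.exists
        assert not (0 <= inter[0] <= p.K1 and 0 <= inter[1] <= p.K2)

    def test_degenerate_grid_rejected(self, s51_params):
        with pytest.raises(ValueError):
            nullclines_2d(s51_params, grid=1)


class TestSeparatrix:
    def test_branches_anchor_at_saddle_and_origin(self, partition, s51_params):
        assert partition.branch_lower[-1] == pytest.approx([250.0, 625.0])
        assert partition.branch_upper[0] == pytest.approx([250.0, 625.0])
        assert np.linalg.norm(partition.branch_lower[0]) < 1e-3 * 1000

    def test_saddle_is_on_curve(self, partition):
        assert partition.classify(partition.M) == "on-curve"

    def test_basins_match_forward_simulation(self, partition, s51_params, rng):
        """Every off-curve sample lands in the basin forward flow confirms."""
        points2d = demand_equilibria_2d(s51_params)
        tested = 0
        for _ in range(30):
            x = rng.uniform(0.02, 0.98, 2) * 1000
            if partition.distance_to_curve(x) <= 1e-3 * 1000:
                continue
            tested += 1
            assert partition.classify(x) == _basin_of(x, s51_params, points2d)
        assert tested >= 20

    def test_near_offline_corner_in_offline_basin(self, partition, s51_params):
        assert partition.classify((0.99 * s51_params.K1, 5.0)) == "Y"

    def test_symmetric_parameters_give_symmetric_curve(self):
        params = ModelParameters(r1=1, r2=1, K1=1000, K2=1000, m=-1.5, n=-1.5,
                                 beta11=1e-5, beta12=1e-5, beta21=1e-5,
                                 beta22=1e-5, gamma1=0.05, gamma2=0.05)
        part = separatrix_2d(params)
        for point in np.vstack([part.branch_lower[::7], part.branch_upper[::7]]):
            assert part.distance_to_curve(point[::-1]) < 1e-3 * 1000

    def test_coexistence_regime_rejected(self, s53_params):
        with pytest.raises(ValueError, match="bistable"):
            separatrix_2d(s53_params)


class TestOmegaRegions:
    def test_interior_point_satisfies_open_regions(self, s51_params, partition):
        labels = omega_region_membership((400.0, 50.0, 300.0, 40.0),
                                         s51_params, partition)
        assert {"Omega1", "Omega4", "Omega5", "Omega8", "Omega9",
                "Omega10", "Omega11"} <= set(labels)

    def test_no_offline_purchasers_excludes_I1_regions(self, s51_params, partition):
        labels = omega_region_membership((400.0, 0.0, 300.0, 40.0),
                                         s51_params, partition)
        assert not {"Omega3", "Omega5", "Omega11", "Omega13"} & set(labels)

    def test_state_over_separatrix_satisfies_manifold_region(
            self, s51_params, partition):
        N1, N2 = partition.M
        labels = omega_region_membership((N1, 10.0, N2, 10.0),
                                         s51_params, partition)
        assert "Omega12" in labels and "Omega13" in labels

    def test_basin_labels_require_partition(self, s51_params):
        with pytest.raises(ValueError, match="partition"):
            omega_region_membership((400.0, 50.0, 300.0, 40.0), s51_params)
        labels = omega_region_membership((400.0, 50.0, 300.0, 40.0),
                                         s51_params, labels=("Omega4", "Omega5"))
        assert labels == ["Omega4", "Omega5"]


def _fast_set(m, n, beta11, beta22, beta12=1e-5, beta21=1e-5):
    return ModelParameters(r1=1.0, r2=1.0, K1=1000.0, K2=1000.0, m=m, n=n,
                           beta11=beta11, beta12=beta12, beta21=beta21,
                           beta22=beta22, gamma1=0.05, gamma2=0.05)


# One fast parameter set per open-region stable condition row.  The low/high
# within-channel rates put R1, R2 on either side of 1; the coexistence pair
# puts Pi1 - Pi2 on either side of 0.
ATTRACTOR_CASES = [
    (_fast_set(-1.5, -1.5, 2e-5, 2e-5), "P1", "Omega2"),
    (_fast_set(-1.5, -1.5, 2e-5, 2e-5), "P3", "Omega6"),
    (_fast_set(-1.5, -1.5, 2.5e-4, 2.5e-4), "P2", "Omega3"),
    (_fast_set(-1.5, -1.5, 2.5e-4, 2.5e-4), "P4", "Omega7"),
    (_fast_set(-0.5, -1.5, 2e-5, 2e-5), "P1", "Omega4"),
    (_fast_set(-0.5, -1.5, 2.5e-4, 2e-5), "P2", "Omega5"),
    (_fast_set(-1.5, -0.5, 2e-5, 2e-5), "P3", "Omega8"),
    (_fast_set(-1.5, -0.5, 2e-5, 2.5e-4), "P4", "Omega9"),
    (_fast_set(-0.5, -0.5, 1e-5, 1e-5), "P5", "Omega10"),
    (_fast_set(-0.5, -0.5, 1e-5, 1e-5, 2e-4, 2e-4), "P6", "Omega11"),
]


@pytest.mark.parametrize("params,target,omega",
                         ATTRACTOR_CASES,
                         ids=[f"{t}-{o}" for _, t, o in ATTRACTOR_CASES])
def test_claimed_attractor_draws_region_states(params, target, omega):
    """20 seeded states inside each claimed Omega region converge to the
    claimed equilibrium — the executable form of the long-run sales table."""
    table = classify_by_conditions(params)
    row = next(r for r in table.rows if r.point == target)
    assert row.omega == omega
    partition = separatrix_2d(params) if row.basin else None
    points = {pt.label: pt for pt in enumerate_equilibria_4d(params)}
    candidates = [pt for pt in points.values() if pt.exists]
    rng = np.random.default_rng(71)
    found = 0
    while found < 20:
        N1, N2 = rng.uniform(0.05, 0.95, 2) * 1000
        if partition is not None and partition.classify((N1, N2)) != row.basin:
            continue
        I1 = rng.uniform(0.1, 1.0) * N1
        I2 = rng.uniform(0.1, 1.0) * N2
        state = np.array([N1, I1, N2, I2])
        query = None if partition is not None else (omega,)
        assert omega in omega_region_membership(state, params, partition,
                                                labels=query)
        ok, got = _converges_to(params, state, points[target], candidates)
        assert ok, f"state {state} reached {got!r}, expected {target}"
        found += 1


def test_basin_oracle_and_partition_agree_on_sampled_bistable_sets():
    """Separatrix-based and simulation-based basin labels coincide."""
    for params in sample_parameters("bistable", 3, seed=83):
        part = separatrix_2d(params)
        points2d = demand_equilibria_2d(params)
        rng = np.random.default_rng(89)
        scale = max(params.K1, params.K2)
        for _ in range(10):
            x = rng.uniform(0.05, 0.95, 2) * [params.K1, params.K2]
            if part.distance_to_curve(x) <= 1e-3 * scale:
                continue
            assert part.classify(x) == _basin_of(x, params, points2d)
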