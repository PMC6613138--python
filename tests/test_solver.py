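"""Radial moving-boundary solver: pressure, diffusion, stepping, diagnostics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import ironfront as irf
from ironfront.solver import halo_profile, iron_budget


def shooting_edge_velocity(g_func, s, lam, n=20000):
    """Independent oracle: integrate r*lam*p' = -int_0^r g r' dr' directly."""
    r = np.linspace(0.0, s, n + 1)
    gr = g_func(r) * r
    cumulative = np.concatenate([[0.0], np.cumsum(0.5 * (gr[1:] + gr[:-1]) * np.diff(r))])
    # v = -lam p'(s) = cumulative(s)/s
    return cumulative[-1] / s


class TestPressureSolve:
    def test_uniform_growth_closed_form(self, grid):
        g0, s, lam = 0.1, 2.0, 1.3
        g = np.full(grid.n_cells, g0)
        r_nodes, p, v = irf.solve_pressure(grid, s, g, lam)
        exact = g0 * (s**2 - r_nodes**2) / (4 * lam)
        assert np.max(np.abs(p - exact)) <= 1e-3 * exact.max()
        assert v == pytest.approx(g0 * s / 2, rel=1e-12)

    def test_no_growth_no_pressure(self, grid):
        _, p, v = irf.solve_pressure(grid, 2.0, np.zeros(grid.n_cells), 1.0)
        assert np.all(p == 0.0)
        assert v == 0.0

    def test_annular_growth_matches_shooting_oracle(self, grid):
        s, w = 2.0, 0.4

        def g_func(r):
            return np.where((r >= s - w) & (r <= s), 0.25, 0.0)

        g = g_func(grid.r)
        _, _, v = irf.solve_pressure(grid, s, g, 1.0)
        v_ref = shooting_edge_velocity(g_func, s, 1.0)
        assert v == pytest.approx(v_ref, rel=5e-3)

    def test_second_order_grid_convergence(self, params):
        g0, s, lam = 0.1, 2.0, 1.0
        errors = []
        sizes = [100, 200, 400]
        for n in sizes:
            grid_n = irf.RadialGrid.from_radius(params.R_dish, n)
            g = np.full(n, g0)
            r_nodes, p, _ = irf.solve_pressure(grid_n, s, g, lam)
            exact = g0 * (s**2 - r_nodes**2) / (4 * lam)
            errors.append(np.max(np.abs(p - exact)) / exact.max())
        order = np.polyfit(np.log(sizes), np.log(errors), 1)[0]
        assert order <= -1.7

    def test_unresolved_footprint_rejected(self, grid):
        with pytest.raises(ValueError, match="finer grid"):
            irf.solve_pressure(grid, grid.dr / 2, np.zeros(grid.n_cells), 1.0)


class TestDiffusionStep:
    def test_uniform_field_unchanged(self, grid):
        f = np.full(grid.n_cells, 3.5)
        out = irf.diffusion_step(f, 0.02, 0.5, grid)
        assert out == pytest.approx(f, rel=1e-12)

    def test_zero_diffusivity_unchanged(self, grid):
        f = np.random.default_rng(0).uniform(0, 1, grid.n_cells)
        assert np.array_equal(irf.diffusion_step(f, 0.0, 0.5, grid), f)

    def test_mass_conserved_and_nonnegative(self, grid):
        f = np.exp(-((grid.r - 1.0) / 0.1) ** 2) * 50
        out = irf.diffusion_step(f, 0.05, 1.0, grid)
        assert grid.total(out) == pytest.approx(grid.total(f), rel=1e-12)
        assert np.all(out >= 0)

    def test_central_pulse_matches_fine_reference(self, params):
        """Repeated coarse steps against a 10x finer grid / 10x smaller dt."""
        D, T = 0.02, 10.0
        coarse = irf.RadialGrid.from_radius(params.R_dish, 300)
        fine = irf.RadialGrid.from_radius(params.R_dish, 3000)

        def pulse(r):
            return np.exp(-((r / 0.15) ** 2))

        fc = pulse(coarse.r)
        for _ in range(100):
            fc = irf.diffusion_step(fc, D, T / 100, coarse)
        ff = pulse(fine.r)
        for _ in range(1000):
            ff = irf.diffusion_step(ff, D, T / 1000, fine)
        ref = np.interp(coarse.r, fine.r, ff)
        l2 = np.sqrt(np.sum((fc - ref) ** 2) / np.sum(ref**2))
        assert l2 <= 0.01


class TestAdvanceAndSimulate:
    def test_pure_growth_front_is_exponential(self, params):
        """With no iron kinetics and F0 >> Fh the front obeys ds/dt = k0*s/2."""
        p = params.replace(kb=0, kp=0, kf=0, F0=1e4, Fh=5.0, s0=0.05)
        grid = irf.RadialGrid.from_radius(p.R_dish, 900)
        t_end = 5 * 2 * np.log(2) / p.kappa0  # five front doublings
        traj = irf.simulate(p, grid, t_end=t_end, sample_every=t_end / 100)
        exact = p.s0 * np.exp(p.kappa0 * traj.times / 2)
        assert traj.front[-1] == pytest.approx(exact[-1], rel=0.01)
        assert np.max(np.abs(traj.front - exact) / exact) <= 0.01

    def test_subcritical_iron_freezes_front(self, params, coarse_grid):
        p = params.replace(F0=0.5, Fc=1.0, Cc=0.005)
        traj = irf.simulate(p, coarse_grid, t_end=30.0)
        assert np.all(traj.front == p.s0)
        assert np.all(traj.area == pytest.approx(np.pi * p.s0**2))
        # acid is still produced and chelates what little iron there is
        assert traj.total_acid[-1] > 0

    def test_front_monotone_nondecreasing(self, producer_traj, mutant_traj):
        for traj in (producer_traj, mutant_traj):
            assert np.all(np.diff(traj.front) >= -1e-12)

    def test_iron_budget_closes_at_every_sample(self, producer_traj, mutant_traj):
        for traj in (producer_traj, mutant_traj):
            closure = np.abs(
                traj.free_iron + traj.chelated_iron + traj.consumed_iron
                - traj.initial_iron
            ) / traj.initial_iron
            assert closure.max() <= 1e-6

    def test_free_iron_never_increases_anywhere(self, producer_traj):
        """No iron sources exist: F(r, t) is nonincreasing in t at every r."""
        snaps = producer_traj.snapshots
        assert len(snaps) >= 3
        for earlier, later in zip(snaps, snaps[1:]):
            assert np.all(later.F <= earlier.F + 1e-9 * earlier.F.max())

    def test_simulation_is_deterministic(self, params, coarse_grid):
        a = irf.simulate(params, coarse_grid, t_end=40.0)
        b = irf.simulate(params, coarse_grid, t_end=40.0)
        assert np.array_equal(a.front, b.front)
        assert np.array_equal(a.free_iron, b.free_iron)
        assert np.array_equal(a.chelated_iron, b.chelated_iron)

    def test_mismatched_grid_rejected(self, params):
        bad = irf.RadialGrid.from_radius(params.R_dish * 2, 100)
        with pytest.raises(ValueError, match="grid radius"):
            irf.simulate(params, bad, t_end=1.0)


class TestArrestDetection:
    @staticmethod
    def _traj(times, front, R=4.5):
        s = np.asarray(front, dtype=float)
        return irf.Trajectory(
            times=np.asarray(times, dtype=float),
            front=s,
            area=np.pi * s**2,
            total_acid=np.zeros_like(s),
            free_iron=np.zeros_like(s),
            chelated_iron=np.zeros_like(s),
            consumed_iron=np.zeros_like(s),
            initial_iron=1.0,
            R_dish=R,
            reached_boundary=bool(s[-1] >= R - 1e-9),
        )

    def test_constant_area_arrests_at_first_sample(self):
        t = np.arange(0.0, 50.0, 1.0)
        res = irf.detect_arrest(self._traj(t, np.full_like(t, 1.0)))
        assert res.arrested and res.time == 0.0

    def test_exponential_growth_is_expanding(self):
        t = np.arange(0.0, 50.0, 1.0)
        res = irf.detect_arrest(self._traj(t, 0.1 * np.exp(0.05 * t)))
        assert not res.arrested

    def test_boundary_reaching_run_is_expanding(self):
        t = np.arange(0.0, 50.0, 1.0)
        s = np.minimum(0.1 * np.exp(0.2 * t), 4.5)
        res = irf.detect_arrest(self._traj(t, s))
        assert not res.arrested

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            irf.detect_arrest(self._traj([0.0, 1.0], [1.0, 1.0]))

    def test_calibrated_producer_arrests_inside_dish(self, producer_traj, params):
        res = irf.detect_arrest(producer_traj)
        assert res.arrested
        assert res.time is not None and res.time < 160.0
        assert res.terminal_area < np.pi * params.R_dish**2


class TestHaloProfile:
    def test_initial_state_has_no_halo(self, params, grid):
        state = irf.initial_state(params, grid)
        h = halo_profile(state, params, grid)
        assert h.r_halo is None and h.halo_width is None
        assert h.iron_depletion_radius is None

    def test_mutant_never_forms_halo(self, mutant_traj, params, grid):
        for state in mutant_traj.snapshots:
            assert np.all(state.C == 0.0)
            assert halo_profile(state, params, grid).r_halo is None

    def test_arrested_producer_halo_beyond_front(self, producer_traj, params, grid):
        state = producer_traj.snapshots[-1]
        h = halo_profile(state, params, grid)
        assert h.r_halo is not None and h.r_halo > state.s
        assert h.iron_depletion_radius is not None
        assert h.iron_depletion_radius > state.s


class TestIronBudget:
    def test_initial_state_balances_exactly(self, params, grid):
        state = irf.initial_state(params, grid)
        free, chel, used, err = iron_budget(state, grid)
        assert chel == 0.0 and used == 0.0 and err == 0.0
        assert free == pytest.approx(np.pi * params.R_dish**2 * params.F0, rel=1e-12)

    def test_no_utilization_means_no_consumption(self, params, coarse_grid):
        p = params.replace(kf=0.0)
        traj = irf.simulate(p, coarse_grid, t_end=30.0)
        assert np.all(traj.consumed_iron == 0.0)

    def test_simulated_state_closure(self, producer_traj, grid):
        _, _, _, err = iron_budget(producer_traj.snapshots[-1], grid)
        assert err <= 1e-6
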