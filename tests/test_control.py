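"""Objective, Hamiltonian, adjoints, control law and the sweep solver."""

import numpy as np
import pytest

from depdyn.control import (
    ControlWeights,
    OCConfig,
    adjoint_rhs,
    forward_backward_sweep,
    hamiltonian,
    objective_J,
    optimal_control_update,
    run_strategies,
)
from depdyn.model import Trajectory, integrate_fixed_step

from conftest import random_valid_params


@pytest.fixture(scope="module")
def scenario(baseline):
    init = baseline.carrying_capacity * np.array([0.94, 0.01, 0.025, 0.025, 0, 0, 0])
    return baseline, init


def fd_state_gradient(x, lam, u, params, weights, h_rel=1e-6):
    grad = np.zeros(7)
    for k in range(7):
        h = h_rel * max(abs(x[k]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        grad[k] = (
            hamiltonian(xp, lam, u, params, weights)
            - hamiltonian(xm, lam, u, params, weights)
        ) / (2 * h)
    return grad


class TestObjective:
    def test_zero_everything_gives_zero(self):
        traj = Trajectory(times=np.linspace(0, 15, 16), states=np.zeros((16, 7)))
        assert objective_J(traj, np.zeros((16, 3)), ControlWeights()) == 0.0

    def test_constant_burden_rectangle_integral(self):
        states = np.zeros((16, 7))
        states[:, 2] = 1.0  # P = 1 throughout
        traj = Trajectory(times=np.linspace(0, 15, 16), states=states)
        assert objective_J(traj, np.zeros((16, 3)), ControlWeights()) == pytest.approx(15.0)

    def test_matches_refined_simpson_quadrature(self):
        """Smooth synthetic state/control profiles: the coarse trapezoid
        value agrees with Simpson's rule on a tenfold finer grid."""
        from scipy.integrate import simpson

        from depdyn.control import _running_cost

        def states_of(t):
            t = np.asarray(t)
            return np.column_stack(
                [(50 + 10 * np.sin(0.4 * t + j)) for j in range(7)]
            )

        def controls_of(t):
            t = np.asarray(t)
            return np.column_stack(
                [0.5 + 0.4 * np.cos(0.3 * t + j) for j in range(3)]
            )

        w = ControlWeights()
        times = np.linspace(0, 15, 151)
        J = objective_J(
            Trajectory(times=times, states=states_of(times)), controls_of(times), w
        )
        fine = np.linspace(0, 15, 1501)
        J_ref = simpson(_running_cost(states_of(fine), controls_of(fine), w), x=fine)
        assert J == pytest.approx(J_ref, rel=1e-4)

    def test_grid_mismatch_rejected(self):
        traj = Trajectory(times=np.linspace(0, 1, 5), states=np.zeros((5, 7)))
        with pytest.raises(ValueError, match="grid"):
            objective_J(traj, np.zeros((4, 3)), ControlWeights())


class TestHamiltonian:
    def test_zero_adjoints_reduce_to_lagrangian(self, scenario):
        params, init = scenario
        w = ControlWeights()
        u = np.array([0.2, 0.3, 0.1])
        H = hamiltonian(init, np.zeros(7), u, params, w)
        expected = (
            init[2] + init[3] + init[4] + init[5]
            + 0.5 * 15 * 0.04 + 0.5 * 40 * 0.09 + 0.5 * 55 * 0.01
        )
        assert H == pytest.approx(expected, rel=1e-12)

    def test_zero_weights_give_adjoint_dot_rhs(self, scenario, rng):
        from depdyn.model import rhs

        params, init = scenario
        w = ControlWeights(state_cost=(0, 0, 0, 0), control_cost=(1, 1, 1))
        lam = rng.standard_normal(7)
        H = hamiltonian(init, lam, np.zeros(3), params, w)
        assert H == pytest.approx(float(lam @ rhs(init, params)), rel=1e-10)

    def test_control_gradient_structure(self, scenario, rng):
        """dH/du_i = W_{4+i} u_i + switching term, checked against central
        differences."""
        params, _ = scenario
        w = ControlWeights()
        x = rng.uniform(10.0, 1e4, size=7)
        lam = rng.standard_normal(7)
        u = rng.uniform(0.1, 0.9, size=3)
        switching = [
            (lam[4] - lam[2]) * x[2],
            (lam[5] - lam[3]) * x[3],
            (lam[6] - lam[5]) * x[5],
        ]
        for j, (Wu, sw) in enumerate(zip(w.control_cost, switching)):
            h = 1e-6
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            dH = (
                hamiltonian(x, lam, up, params, w) - hamiltonian(x, lam, um, params, w)
            ) / (2 * h)
            assert dH == pytest.approx(Wu * u[j] + sw, rel=1e-5, abs=1e-6 * abs(dH))


class TestAdjoint:
    def test_matches_fd_hamiltonian_gradient(self, rng):
        for _ in range(20):
            params = random_valid_params(rng)
            w = ControlWeights()
            x = rng.uniform(1.0, 1e4, size=7)
            lam = rng.standard_normal(7) * 10
            u = rng.uniform(0, 1, size=3)
            got = adjoint_rhs(x, lam, u, params, w)
            want = -fd_state_gradient(x, lam, u, params, w)
            scale = max(1.0, np.abs(want).max())
            assert np.max(np.abs(got - want)) < 1e-6 * scale

    def test_state_cost_enters_one_component(self, scenario, rng):
        """Raising W1 changes only the P-adjoint equation, by exactly the
        increment."""
        params, _ = scenario
        x = rng.uniform(1.0, 1e3, size=7)
        lam = rng.standard_normal(7)
        u = np.zeros(3)
        base = adjoint_rhs(x, lam, u, params, ControlWeights())
        bumped = adjoint_rhs(
            x, lam, u, params, ControlWeights(state_cost=(1.5, 1, 1, 1))
        )
        diff = bumped - base
        assert diff[2] == pytest.approx(-0.5, rel=1e-12)
        assert np.allclose(np.delete(diff, 2), 0.0)

    def test_zero_weights_zero_adjoints_stationary(self, scenario):
        params, init = scenario
        w = ControlWeights(state_cost=(0, 0, 0, 0))
        out = adjoint_rhs(init, np.zeros(7), np.zeros(3), params, w)
        assert np.allclose(out, 0.0)

    def test_printed_transcription_flags_known_deviations(self, scenario, rng):
        """The verbatim printed adjoint system deviates from the exact
        Hamiltonian gradient (it is retained as a cross-check only)."""
        from depdyn.control import adjoint_rhs_printed

        params, _ = scenario
        w = ControlWeights()
        x = rng.uniform(10.0, 1e4, size=7)
        lam = rng.standard_normal(7)
        u = rng.uniform(0, 1, size=3)
        exact = adjoint_rhs(x, lam, u, params, w)
        printed = adjoint_rhs_printed(x, lam, u, params, w)
        assert not np.allclose(exact, printed, rtol=1e-6)


class TestControlUpdate:
    def test_zero_switching_function(self):
        lam = np.zeros(7)
        u = optimal_control_update(np.ones(7), lam, ControlWeights())
        assert np.allclose(u, 0.0)

    def test_upper_clip(self):
        lam = np.zeros(7)
        lam[2] = 105.0  # (lam3 - lam5) P / W5 = 7 with P = 1, W5 = 15
        u = optimal_control_update(np.ones(7), lam, ControlWeights())
        assert u[0] == 1.0

    def test_mask_forces_inactive_controls_to_zero(self):
        lam = np.ones(7) * 5
        lam[4] = lam[5] = lam[6] = 0.0
        u = optimal_control_update(
            np.ones(7) * 10, lam, ControlWeights(), mask=(True, False, False)
        )
        assert u[1] == 0.0 and u[2] == 0.0

    def test_clip_matches_grid_search(self, scenario, rng):
        """The projected update minimises the single-control Hamiltonian
        restriction over a dense grid of the box."""
        params, _ = scenario
        w = ControlWeights()
        for _ in range(5):
            x = rng.uniform(1.0, 1e3, size=7)
            lam = rng.standard_normal(7) * rng.choice([0.1, 10.0])
            u_star = optimal_control_update(x, lam, w)
            grid = np.linspace(0, 1, 2001)
            for j in range(3):
                values = []
                for g in grid:
                    u = u_star.copy()
                    u[j] = g
                    values.append(hamiltonian(x, lam, u, params, w))
                assert u_star[j] == pytest.approx(grid[np.argmin(values)], abs=1e-3)


class TestSweep:
    def test_frozen_zero_controls_reduce_to_plain_simulation(self, scenario):
        params, init = scenario
        w = ControlWeights(upper=(0.0, 0.0, 0.0))
        cfg = OCConfig(n_grid=151)
        res = forward_backward_sweep(params, init, w, cfg)
        assert res.converged
        assert np.allclose(res.controls, 0.0)
        times = res.trajectory.times
        ref = integrate_fixed_step(params, init, times, max_step=times[1] - times[0])
        assert np.allclose(res.trajectory.states, ref, rtol=1e-10)
        J_ref = objective_J(Trajectory(times=times, states=ref), res.controls, w)
        assert res.objective == pytest.approx(J_ref)

    def test_optimal_improves_on_no_control(self, scenario):
        params, init = scenario
        w = ControlWeights()
        cfg = OCConfig(n_grid=301)
        res = forward_backward_sweep(params, init, w, cfg)
        assert res.converged
        times = res.trajectory.times
        zero = np.zeros((times.size, 3))
        states0 = integrate_fixed_step(params, init, times, controls=zero,
                                       max_step=times[1] - times[0])
        J0 = objective_J(Trajectory(times=times, states=states0), zero, w)
        assert res.objective < J0
        # transversality holds exactly by construction
        assert np.all(res.adjoints[-1] == 0.0)
        # bounds respected everywhere
        assert res.controls.min() >= 0.0 and res.controls.max() <= 1.0

    def test_costlier_controls_shrink(self, scenario):
        params, init = scenario
        cfg = OCConfig(n_grid=151, tolerance=1e-5)
        cheap = forward_backward_sweep(params, init, ControlWeights(), cfg)
        costly = forward_backward_sweep(
            params,
            init,
            ControlWeights(control_cost=(1500.0, 4000.0, 5500.0)),
            cfg,
        )
        assert np.all(costly.controls <= cheap.controls + 1e-6)
        assert costly.controls.sum() < cheap.controls.sum()


@pytest.fixture(scope="module")
def comparison(baseline):
    init = baseline.carrying_capacity * np.array([0.94, 0.01, 0.025, 0.025, 0, 0, 0])
    return run_strategies(baseline, init, ControlWeights(), OCConfig(n_grid=301))


class TestStrategies:

    def test_baseline_row_matches_plain_simulation(self, scenario, comparison):
        params, init = scenario
        row = comparison.table.set_index("strategy").loc["baseline"]
        times = comparison.results["baseline"].trajectory.times
        ref = integrate_fixed_step(params, init, times, max_step=times[1] - times[0])
        assert row["D_at_tf"] == pytest.approx(ref[-1, 3], rel=1e-12)

    def test_masks_partition_controls(self, comparison):
        res_a = comparison.results["A"]
        assert np.allclose(res_a.controls[:, 1:], 0.0)
        assert res_a.controls[:, 0].max() > 0

    def test_full_strategy_attains_lowest_final_burden(self, comparison):
        table = comparison.table.set_index("strategy")
        d_tf = table.loc[list("ABCDEFG"), "D_at_tf"]
        assert d_tf.idxmin() == "G"

    def test_combined_strategies_beat_components_in_objective(self, comparison):
        """Enlarging the admissible control set can only improve the optimal
        objective: each two-control strategy beats both of its single-control
        components, and G beats everything."""
        J = comparison.table.set_index("strategy")["J"]
        pairs = {"D": ("A", "B"), "E": ("B", "C"), "F": ("A", "C")}
        for combo, parts in pairs.items():
            for single in parts:
                assert J[combo] <= J[single] * (1 + 1e-6)
        assert J["G"] <= J[list("ABCDEF")].min() * (1 + 1e-6)
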