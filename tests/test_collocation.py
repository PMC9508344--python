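"""Flipped-LGR transcription: nodes, quadrature, analytic optimal control."""
import numpy as np
import pytest

from sprintopt import collocation as coll


class TestNodes:
    def test_first_order_is_implicit_euler(self):
        nodes, weights = coll.lgr_nodes(1)
        assert nodes.tolist() == [1.0]
        assert weights.tolist() == [1.0]

    def test_third_order_nodes_and_weights(self):
        nodes, weights = coll.lgr_nodes(3)
        assert nodes == pytest.approx([0.1550510, 0.6449490, 1.0], abs=1e-6)
        assert weights == pytest.approx([0.3764030, 0.5124858, 0.1111111], abs=1e-6)

    @pytest.mark.parametrize("d", range(1, 7))
    def test_weights_sum_to_one(self, d):
        _, w = coll.lgr_nodes(d)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_quadrature_exact_to_degree_2d_minus_2(self, d, rng):
        nodes, w = coll.lgr_nodes(d)
        for _ in range(100):
            deg = int(rng.integers(0, 2 * d - 1))
            c = rng.normal(0, 1, deg + 1)
            poly = np.polynomial.Polynomial(c)
            exact = poly.integ()(1.0) - poly.integ()(0.0)
            assert w @ poly(nodes) == pytest.approx(exact, abs=1e-10)

    def test_rejects_zero_order(self):
        with pytest.raises(ValueError):
            coll.lgr_nodes(0)


class TestDifferentiation:
    def test_constant_has_zero_derivative(self):
        pts = np.array([0.0, 0.2, 0.7, 1.0])
        D = coll.lagrange_differentiation(pts)
        assert np.abs(D @ np.ones(4)).max() < 1e-12

    def test_linear_has_unit_derivative(self):
        pts = np.array([0.0, 0.2, 0.7, 1.0])
        D = coll.lagrange_differentiation(pts)
        assert D @ pts == pytest.approx(np.ones(4), abs=1e-12)

    def test_cubic_derivative_exact_on_lgr_points(self):
        nodes, _ = coll.lgr_nodes(3)
        pts = np.concatenate([[0.0], nodes])
        D = coll.lagrange_differentiation(pts, at=nodes)
        vals = pts**3
        assert D @ vals == pytest.approx(3 * nodes**2, abs=1e-12)

    def test_rejects_duplicate_nodes(self):
        with pytest.raises(ValueError):
            coll.lagrange_differentiation(np.array([0.0, 0.5, 0.5]))


def double_integrator_ocp(u_bound=20.0):
    return dict(
        nx=2, nu=1,
        A_x=np.array([[0.0, 1.0], [0.0, 0.0]]),
        A_u=np.array([[0.0], [1.0]]),
        x_lb=np.array([-2.0, -5.0]), x_ub=np.array([2.0, 5.0]),
        u_lb=np.array([-u_bound]), u_ub=np.array([u_bound]),
        boundary=lambda x0, xf, tf: np.concatenate([x0, xf - np.array([1.0, 0.0])]),
        boundary_lb=np.zeros(4), boundary_ub=np.zeros(4),
    )


class TestMinimumEffort:
    def test_piecewise_constant_optimum_matches_closed_form(self):
        # with controls constant per interval the discrete optimum of
        # min \int u^2, x: 0 -> 1 rest-to-rest on [0, 1] is 12 N^2/(N^2-1)
        N = 10
        ocp = coll.OCPDefinition(
            **double_integrator_ocp(),
            quad_residuals=lambda x, u, s, tf: u.copy(),
            term_slices={"effort": slice(0, 1)},
        )
        mesh = coll.Mesh(N, 3, 1.0)
        tr = coll.transcribe(ocp, mesh)
        guess = (np.zeros((N, 4, 2)), np.zeros((N, 1)), 1.0)
        sol = coll.solve(tr, guess, tol=1e-8, maxiter=300)
        assert sol.success
        assert sol.objective == pytest.approx(12.0 * N**2 / (N**2 - 1), abs=1e-4)

    def test_linear_control_refinement_reaches_analytic_twelve(self):
        # lifting the control into the state (its rate becomes the control)
        # removes the piecewise-constant restriction: cost -> exactly 12
        N = 10
        A_x = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        A_u = np.array([[0.0], [0.0], [1.0]])
        ocp = coll.OCPDefinition(
            nx=3, nu=1, A_x=A_x, A_u=A_u,
            x_lb=np.array([-2.0, -5.0, -30.0]), x_ub=np.array([2.0, 5.0, 30.0]),
            u_lb=np.array([-200.0]), u_ub=np.array([200.0]),
            boundary=lambda x0, xf, tf: np.concatenate(
                [x0[:2], xf[:2] - np.array([1.0, 0.0])]
            ),
            boundary_lb=np.zeros(4), boundary_ub=np.zeros(4),
            quad_residuals=lambda x, u, s, tf: np.array([x[2]]),
            term_slices={"effort": slice(0, 1)},
        )
        mesh = coll.Mesh(N, 3, 1.0)
        tr = coll.transcribe(ocp, mesh)
        guess = (np.zeros((N, 4, 3)), np.zeros((N, 1)), 1.0)
        sol = coll.solve(tr, guess, tol=1e-8, maxiter=300)
        assert sol.success
        assert sol.objective == pytest.approx(12.0, abs=1e-3)

    def test_mesh_refinement_error_decreases_monotonically(self):
        errors = []
        for N in (5, 10, 20, 40):
            ocp = coll.OCPDefinition(
                **double_integrator_ocp(),
                quad_residuals=lambda x, u, s, tf: u.copy(),
            )
            tr = coll.transcribe(ocp, coll.Mesh(N, 3, 1.0))
            sol = coll.solve(tr, (np.zeros((N, 4, 2)), np.zeros((N, 1)), 1.0),
                             tol=1e-9, maxiter=300)
            errors.append(abs(sol.objective - 12.0))
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))


class TestMinimumTime:
    def test_bang_bang_final_time(self):
        N = 40
        ocp = coll.OCPDefinition(
            **double_integrator_ocp(u_bound=1.0),
            mayer=lambda x0, xf, tf: tf,
        )
        mesh = coll.Mesh(N, 3, (0.5, 5.0))
        tr = coll.transcribe(ocp, mesh)
        guess = (np.tile([0.5, 0.0], (N, 4, 1)), np.zeros((N, 1)), 2.5)
        sol = coll.solve(tr, guess, tol=1e-6, maxiter=400)
        assert sol.success
        assert abs(sol.t_final - 2.0) < 2.0 / N

    def test_free_time_with_pinned_bounds_matches_fixed_time(self):
        N = 8

        def build(tfinal):
            ocp = coll.OCPDefinition(
                **double_integrator_ocp(),
                quad_residuals=lambda x, u, s, tf: u.copy(),
            )
            tr = coll.transcribe(ocp, coll.Mesh(N, 3, tfinal))
            return coll.solve(tr, (np.zeros((N, 4, 2)), np.zeros((N, 1)), 1.0),
                              tol=1e-9, maxiter=300)

        fixed = build(1.0)
        pinned = build((1.0, 1.0))
        assert pinned.t_final == pytest.approx(1.0, abs=1e-12)
        assert pinned.objective == pytest.approx(fixed.objective, abs=1e-6)


class TestTranscriptionBasics:
    def test_zero_dynamics_keeps_state_constant(self):
        c = 0.7
        ocp = coll.OCPDefinition(
            nx=1, nu=1,
            A_x=np.zeros((1, 1)), A_u=np.zeros((1, 1)),
            x_lb=np.array([-2.0]), x_ub=np.array([2.0]),
            u_lb=np.array([-1.0]), u_ub=np.array([1.0]),
            boundary=lambda x0, xf, tf: np.array([x0[0] - c]),
            boundary_lb=np.zeros(1), boundary_ub=np.zeros(1),
            quad_residuals=lambda x, u, s, tf: u.copy(),
        )
        tr = coll.transcribe(ocp, coll.Mesh(6, 3, 1.0))
        sol = coll.solve(tr, (np.full((6, 4, 1), 0.0), np.zeros((6, 1)), 1.0),
                         tol=1e-9, maxiter=100)
        assert np.abs(sol.states - c).max() < 1e-6

    def test_scaling_invariance(self):
        # the same physical problem expressed in 1e3-scaled units must give
        # the identical unscaled solution
        N = 10

        def build(scale):
            ocp = coll.OCPDefinition(
                nx=2, nu=1,
                A_x=np.array([[0.0, 1.0], [0.0, 0.0]]),
                A_u=np.array([[0.0], [1.0 / scale]]),  # u in scaled units
                x_lb=np.array([-2.0, -5.0]), x_ub=np.array([2.0, 5.0]),
                u_lb=np.array([-20.0 * scale]), u_ub=np.array([20.0 * scale]),
                boundary=lambda x0, xf, tf: np.concatenate(
                    [x0, xf - np.array([1.0, 0.0])]
                ),
                boundary_lb=np.zeros(4), boundary_ub=np.zeros(4),
                quad_residuals=lambda x, u, s, tf, sc=scale: u / sc,
            )
            tr = coll.transcribe(ocp, coll.Mesh(N, 3, 1.0))
            return coll.solve(tr, (np.zeros((N, 4, 2)), np.zeros((N, 1)), 1.0),
                              tol=1e-9, maxiter=300)

        s1 = build(1.0)
        s2 = build(1e3)
        assert np.abs(s1.states - s2.states).max() < 1e-6
        assert np.abs(s1.controls - s2.controls / 1e3).max() < 1e-6

    def test_continuity_exact_at_solution(self):
        N = 10
        ocp = coll.OCPDefinition(
            **double_integrator_ocp(),
            quad_residuals=lambda x, u, s, tf: u.copy(),
        )
        tr = coll.transcribe(ocp, coll.Mesh(N, 3, 1.0))
        sol = coll.solve(tr, (np.zeros((N, 4, 2)), np.zeros((N, 1)), 1.0),
                         tol=1e-9, maxiter=300)
        gaps = sol.states[:-1, -1, :] - sol.states[1:, 0, :]
        assert np.abs(gaps).max() < 1e-8

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            coll.OCPDefinition(
                nx=1, nu=1, A_x=np.zeros((1, 1)), A_u=np.zeros((1, 1)),
                x_lb=np.array([1.0]), x_ub=np.array([-1.0]),
                u_lb=np.array([0.0]), u_ub=np.array([0.0]),
            )
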