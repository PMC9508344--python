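"""Hill-type muscle model: curves, geometry, equilibrium, activation."""
import numpy as np
import pytest
from scipy.optimize import brentq

from sprintopt.muscle import (
    ActivationParams,
    HillCurves,
    MTUParams,
    MuscleState,
    activation_ode_rate,
    activation_rate_constraints,
    default_leg_muscles,
    hill_equilibrium_residual,
    mtu_geometry,
    muscle_moments,
)


@pytest.fixture(scope="module")
def curves():
    return HillCurves()


@pytest.fixture(scope="module")
def leg():
    return default_leg_muscles("r")


class TestCurves:
    def test_normalization_anchors(self, curves):
        assert curves.active_force_length(1.0) == pytest.approx(1.0, abs=1e-12)
        assert curves.force_velocity_curve(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_tendon_inverse_round_trip(self, curves):
        for f in np.linspace(0.01, 1.8, 40):
            assert curves.tendon_force(curves.tendon_inverse(f)) == pytest.approx(f, abs=1e-9)

    def test_tendon_force_zero_below_slack(self, curves):
        slack = curves.tendon_slack_force
        assert curves.tendon_force(1.0) == pytest.approx(slack, abs=1e-12)
        assert curves.tendon_force(0.98) < slack

    def test_curves_are_smooth(self, curves):
        # C1: central difference of the derivative estimate stays bounded
        xs = np.linspace(0.6, 1.6, 400)
        d2 = np.diff(curves.active_force_length(xs), 2)
        assert np.abs(d2).max() < 0.1


class TestGeometry:
    def test_constant_polynomial_has_no_moment_arm(self):
        p = MTUParams("m", ["j"], 100.0, 0.1, 0.2, poly_coeffs={"j": [0.3]})
        L, vel, arms = mtu_geometry({"j": 0.5}, p, {"j": 2.0})
        assert arms["j"] == 0.0
        assert vel == 0.0

    def test_linear_polynomial_gives_constant_moment_arm(self):
        r = 0.04
        p = MTUParams("m", ["j"], 100.0, 0.1, 0.2, base_length=0.3,
                      poly_coeffs={"j": [0.0, -r]})
        for qv in (-0.5, 0.0, 1.0):
            _, _, arms = mtu_geometry({"j": qv}, p)
            assert arms["j"] == pytest.approx(r)

    def test_moment_arm_matches_finite_difference_of_length(self, rng):
        coeffs = rng.normal(0, 0.02, 4)
        p = MTUParams("m", ["j"], 100.0, 0.1, 0.2, base_length=0.3,
                      poly_coeffs={"j": list(coeffs)})
        h = 1e-6
        for qv in rng.uniform(-1, 1, 5):
            Lp, _, _ = mtu_geometry({"j": qv + h}, p)
            Lm, _, _ = mtu_geometry({"j": qv - h}, p)
            _, _, arms = mtu_geometry({"j": qv}, p)
            assert arms["j"] == pytest.approx(-(Lp - Lm) / (2 * h), abs=1e-7)

    def test_out_of_range_coordinate_logs_warning(self, caplog):
        p = MTUParams("m", ["j"], 100.0, 0.1, 0.2, base_length=0.3,
                      poly_coeffs={"j": [0.0, -0.04]}, q_range={"j": (-1.0, 1.0)})
        import logging

        with caplog.at_level(logging.WARNING, logger="sprintopt.muscle"):
            mtu_geometry({"j": 2.0}, p)
        assert any("extrapolating" in r.message for r in caplog.records)


class TestHillEquilibrium:
    def test_slack_inactive_muscle_equilibrium_at_zero_force(self, curves):
        # fiber short enough that the passive force vanishes
        p = MTUParams("m", ["j"], 1000.0, 0.10, 0.20, base_length=0.28,
                      poly_coeffs={"j": [0.0, -0.04]})
        q = {"j": 0.0}
        v = {"j": 0.0}
        # at ft=0 the tendon sits below slack length; the equilibrium is at
        # (near) zero force up to the small negative tail of the passive
        # force-length curve below optimal fiber length
        r = hill_equilibrium_residual(q, v, MuscleState(1e-9, 0.0), p, curves)
        assert abs(r) < 0.02

    def test_isometric_optimum_equilibrium(self, curves):
        p = MTUParams("m", [], 1000.0, 0.10, 0.20, pennation_opt=0.0)
        p0 = curves.passive_force_length(1.0)
        ft = 1.0 + p0
        # choose the MTU length so the fiber sits exactly at optimum
        lt = 0.20 * curves.tendon_inverse(ft)
        p.base_length = lt + 0.10
        r = hill_equilibrium_residual({}, {}, MuscleState(ft, 1.0), p, curves)
        assert abs(r) < 1e-12

    def test_residual_matches_straight_line_reevaluation(self, curves, rng):
        p = MTUParams("m", ["j"], 1000.0, 0.11, 0.25, pennation_opt=0.15,
                      base_length=0.36, poly_coeffs={"j": [0.0, -0.05]})
        for _ in range(5):
            qv, vv = rng.uniform(-0.5, 0.5), rng.uniform(-2, 2)
            ft, a = rng.uniform(0.1, 1.2), rng.uniform(0, 1)
            dft = rng.uniform(-5, 5)
            r = hill_equilibrium_residual({"j": qv}, {"j": vv}, MuscleState(ft, a),
                                          p, curves, dft)
            # independent re-evaluation of the stated formulas
            l_mt = p.base_length - 0.05 * qv
            v_mt = -0.05 * vv
            l_t = p.l_slack * curves.tendon_inverse(ft)
            w = p.l_opt * np.sin(p.pennation_opt)
            l_m = np.sqrt((l_mt - l_t) ** 2 + w**2)
            cos_t = (l_mt - l_t) / l_m
            v_t = p.l_slack * dft / (curves.tendon["kT"] * (ft + curves.tendon["c3"]))
            v_norm = (v_mt - v_t) * cos_t / (p.vmax * p.l_opt)
            expect = ft - cos_t * (
                a * curves.active_force_length(l_m / p.l_opt)
                * curves.force_velocity_curve(v_norm)
                + curves.passive_force_length(l_m / p.l_opt)
            )
            assert r == pytest.approx(expect, abs=1e-10)

    def test_unique_equilibrium_root_in_tendon_force(self, curves, leg):
        for p in leg:
            q = {d: 0.1 for d in p.dofs}
            v = {d: 0.0 for d in p.dofs}

            def f(ft):
                return hill_equilibrium_residual(q, v, MuscleState(ft, 0.6), p, curves)

            grid = np.linspace(1e-6, 3.0, 300)
            vals = np.array([f(x) for x in grid])
            crossings = np.sum(np.diff(np.sign(vals)) != 0)
            assert crossings == 1
            root = brentq(f, 1e-6, 3.0)
            assert 0 < root < 2


class TestActivationDynamics:
    def test_resting_muscle_is_feasible(self):
        p = ActivationParams()
        lo, hi = activation_rate_constraints(0.0, 0.0, p)
        assert lo == pytest.approx(0.0)
        assert hi == pytest.approx(-1.0 / 0.015, rel=1e-9)  # -66.67 1/s

    def test_deactivation_boundary(self):
        p = ActivationParams()
        lo, _ = activation_rate_constraints(0.5, -0.5 / 0.060, p)
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_cannot_activate_beyond_full(self):
        p = ActivationParams()
        _, hi = activation_rate_constraints(1.0, 1.0, p)
        assert hi == pytest.approx(1.0)
        assert hi > 0  # infeasible

    def test_ode_rates_lie_inside_inequality_region(self):
        # grid over activation x excitation: the cited first-order ODE rate
        # always satisfies both inequality constraints
        p = ActivationParams()
        for a in np.linspace(0.0, 1.0, 50):
            for e in np.linspace(0.0, 1.0, 50):
                rate = activation_ode_rate(a, e, p)
                lo, hi = activation_rate_constraints(a, rate, p)
                assert lo >= -1e-12
                assert hi <= 1e-12

    def test_requires_activation_faster_than_deactivation(self):
        with pytest.raises(ValueError):
            ActivationParams(tau_act=0.1, tau_deact=0.05)


class TestMuscleMoments:
    def test_zero_forces_give_zero_moments(self, leg):
        states = [MuscleState(0.0, 0.0) for _ in leg]
        out = muscle_moments({d: 0.0 for p in leg for d in p.dofs}, states, leg,
                             ["hip_r", "knee_r", "ankle_r"])
        assert np.abs(out).max() == 0.0

    def test_single_muscle_moment_is_force_times_arm(self):
        p = MTUParams("m", ["j"], 1000.0, 0.1, 0.2, base_length=0.3,
                      poly_coeffs={"j": [0.0, -0.04]})
        out = muscle_moments({"j": 0.0}, [MuscleState(0.5, 0.5)], [p], ["j"])
        assert out[0] == pytest.approx(0.5 * 1000.0 * 0.04)  # 20 N m

    def test_antagonists_cancel(self):
        p1 = MTUParams("f", ["j"], 1000.0, 0.1, 0.2, base_length=0.3,
                       poly_coeffs={"j": [0.0, -0.04]})
        p2 = MTUParams("e", ["j"], 1000.0, 0.1, 0.2, base_length=0.3,
                       poly_coeffs={"j": [0.0, 0.04]})
        out = muscle_moments({"j": 0.1}, [MuscleState(0.5, 0.5)] * 2, [p1, p2], ["j"])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_moments_match_virtual_work_identity(self, leg, rng):
        # for constant forces, tau_j = -d(sum F * length)/dq_j; the work
        # derivative is taken by complex step so the identity is checked to
        # machine precision regardless of the random state
        dofs = ["hip_r", "knee_r", "ankle_r"]
        states = [MuscleState(float(f), 0.5) for f in rng.uniform(0.1, 1.0, len(leg))]
        q0 = {d: float(v) for d, v in zip(dofs, rng.uniform(-0.3, 0.3, 3))}

        def work(qq):
            return sum(
                st.ft_norm * p.fmax * mtu_geometry(
                    {k: qq.get(k, 0.0) for k in p.dofs}, p)[0]
                for st, p in zip(states, leg)
            )

        tau = muscle_moments({**{k: 0.0 for p in leg for k in p.dofs}, **q0},
                             states, leg, dofs)
        h = 1e-100
        for d in dofs:
            qp = dict(q0)
            qp[d] = qp[d] + 1j * h
            cs = -np.imag(work(qp)) / h
            assert tau[dofs.index(d)] == pytest.approx(cs, abs=1e-8)
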