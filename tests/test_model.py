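"""Planar multibody dynamics: closed forms, symbolic oracle, contact laws."""
import numpy as np
import pytest

from sprintopt.model import (
    ContactSphereParams,
    DragParams,
    GeneralizedState,
    Joint,
    ModelSpec,
    Segment,
    aerodynamic_drag,
    com_state,
    contact_grf,
    default_model,
    eom_residual,
    forward_kinematics,
    hunt_crossley_force,
    inverse_dynamics,
    mass_matrix,
    mtp_spring_moment,
    sphere_forces,
)


def pendulum_model(mass=2.0, length=1.0):
    """Near-massless floating base carrying a uniform-rod pendulum."""
    segs = [
        Segment("base", 1e-6, 1e-9, 0.1, (0.0, 0.0)),
        Segment("rod", mass, mass * (0.5 * length) ** 2, length, (0.0, -0.5 * length)),
    ]
    joints = [Joint("j", "base", "rod", (0.0, 0.0))]
    return ModelSpec(segs, joints, gravity=9.81)


def chain_model():
    segs = [
        Segment("s0", 3.0, 0.05, 0.4, (0.1, -0.2)),
        Segment("s1", 2.0, 0.03, 0.35, (0.0, -0.18)),
        Segment("s2", 1.0, 0.01, 0.3, (0.02, -0.15)),
    ]
    joints = [Joint("j1", "s0", "s1", (0.0, -0.4)), Joint("j2", "s1", "s2", (0.05, -0.35))]
    return ModelSpec(segs, joints, gravity=9.81)


class TestEquationOfMotion:
    def test_static_pendulum_joint_row_balances_gravity_torque(self):
        m = pendulum_model()
        theta = 0.3
        q = np.array([0.0, 0.0, 0.0, theta])
        zero = np.zeros(4)
        tau = 2.0 * 9.81 * 0.5 * np.sin(theta)
        r = eom_residual(m, GeneralizedState(q, zero), zero, np.array([tau]),
                         np.zeros(0), np.zeros(2))
        assert abs(r[3]) < 1e-12
        # without the torque, the joint row equals m g (l/2) sin(theta)
        r0 = eom_residual(m, GeneralizedState(q, zero), zero, np.array([0.0]),
                          np.zeros(0), np.zeros(2))
        assert r0[3] == pytest.approx(tau, abs=1e-12)

    def test_ballistic_free_fall_is_dynamically_consistent(self, model):
        q = np.zeros(model.nq)
        q[1] = 1.5  # well above the ground: no contact
        vdot = np.zeros(model.nq)
        vdot[1] = -model.gravity
        r = eom_residual(model, GeneralizedState(q, np.zeros(model.nq)), vdot,
                         np.zeros(model.nq - 3),
                         np.zeros(2 * len(model.contact_spheres)), np.zeros(2))
        assert np.abs(r).max() < 1e-9

    def test_residual_linear_in_accelerations_torques_and_forces(self, model, rng):
        q = rng.normal(0, 0.3, model.nq)
        q[1] += 1.5
        v = rng.normal(0, 1, model.nq)
        st = GeneralizedState(q, v)
        n_int = model.nq - 3
        nsph = len(model.contact_spheres)

        def res(a, tau, grf, drag):
            return eom_residual(model, st, a, tau, grf, drag)

        a1, a2 = rng.normal(0, 1, (2, model.nq))
        t1, t2 = rng.normal(0, 10, (2, n_int))
        g1, g2 = rng.normal(0, 100, (2, 2 * nsph))
        d1, d2 = rng.normal(0, 5, (2, 2))
        lhs = res(a1 + a2, t1 + t2, g1 + g2, d1 + d2)
        rhs = res(a1, t1, g1, d1) + res(a2, t2, g2, d2) - res(
            np.zeros(model.nq), np.zeros(n_int), np.zeros(2 * nsph), np.zeros(2)
        )
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_matches_symbolic_lagrangian_on_three_dof_chain(self, rng):
        sympy = pytest.importorskip("sympy")
        sp = sympy
        cm = chain_model()
        nq = cm.nq
        t = sp.symbols("t")
        qf = [sp.Function(f"q{i}")(t) for i in range(nq)]

        def rot(a):
            return sp.Matrix([[sp.cos(a), -sp.sin(a)], [sp.sin(a), sp.cos(a)]])

        origin = {0: sp.Matrix([qf[0], qf[1]])}
        phi = {0: qf[2]}
        for k, j in enumerate(cm.joints):
            p = cm.segment_index(j.parent)
            c = cm.segment_index(j.child)
            origin[c] = origin[p] + rot(phi[p]) @ sp.Matrix(j.location)
            phi[c] = phi[p] + qf[3 + k]
        L = 0
        for i, s in enumerate(cm.segments):
            cpos = origin[i] + rot(phi[i]) @ sp.Matrix(s.com_offset)
            cd = cpos.diff(t)
            w = phi[i].diff(t)
            L += (sp.Rational(1, 2) * s.mass * (cd.T @ cd)[0, 0]
                  + sp.Rational(1, 2) * s.inertia * w**2
                  - s.mass * sp.Float(9.81) * cpos[1])
        eqs = [sp.diff(sp.diff(L, qf[i].diff(t)), t) - sp.diff(L, qf[i])
               for i in range(nq)]
        lam = sp.lambdify(
            sum(([qf[i], qf[i].diff(t), qf[i].diff(t, 2)] for i in range(nq)), []),
            eqs, "numpy",
        )
        for _ in range(20):
            qn = rng.uniform(-1, 1, nq)
            vn = rng.uniform(-1, 1, nq)
            an = rng.uniform(-1, 1, nq)
            args = sum(([qn[i], vn[i], an[i]] for i in range(nq)), [])
            oracle = np.array(lam(*args), dtype=float)
            mine = inverse_dynamics(cm, qn, vn, an)
            assert np.abs(oracle - mine).max() < 1e-8

    def test_flight_phase_energy_conservation_rk4(self, model):
        # forward-integrate M(q) a = -C - G with no external forces
        q0 = np.zeros(model.nq)
        q0[1] = 2.0
        v0 = np.zeros(model.nq)
        v0[0] = 3.0
        v0[3:] = 0.5

        def accel(q, v):
            rhs = -inverse_dynamics(model, q, v, np.zeros(model.nq))
            return np.linalg.solve(mass_matrix(model, q), rhs)

        def energy(q, v):
            kin = forward_kinematics(model, q, v)
            e = 0.0
            for i, s in enumerate(model.segments):
                e += 0.5 * s.mass * kin.com_vel[i] @ kin.com_vel[i]
                e += 0.5 * s.inertia * kin.omega[i] ** 2
                e += s.mass * model.gravity * kin.com[i][1]
            return e

        dt = 1e-4
        q, v = q0.copy(), v0.copy()
        e0 = energy(q, v)
        for _ in range(1000):
            k1q, k1v = v, accel(q, v)
            k2q, k2v = v + 0.5 * dt * k1v, accel(q + 0.5 * dt * k1q, v + 0.5 * dt * k1v)
            k3q, k3v = v + 0.5 * dt * k2v, accel(q + 0.5 * dt * k2q, v + 0.5 * dt * k2v)
            k4q, k4v = v + dt * k3v, accel(q + dt * k3q, v + dt * k3v)
            q = q + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
            v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        assert abs(energy(q, v) - e0) / abs(e0) < 1e-6


class TestContact:
    def test_separated_sphere_force_negligible(self):
        sph = ContactSphereParams("foot", (0.0, 0.0), 0.02)
        f = hunt_crossley_force(sph, (0.0, 0.1), (0.0, 0.0))
        bound = 1e-6 * sph.stiffness * sph.penetration_smoothing ** 1.5
        assert abs(f[1]) < bound
        assert abs(f[0]) < bound

    def test_static_penetration_closed_form(self):
        # k * delta^1.5 at 1 mm with negligible smoothing
        sph = ContactSphereParams("foot", (0.0, 0.0), 0.02,
                                  penetration_smoothing=1e-8)
        f = hunt_crossley_force(sph, (0.0, 0.02 - 0.001), (0.0, 0.0))
        # 94.87 N up to the smooth clamp of the dissipation bracket (+0.06%)
        assert f[1] == pytest.approx(3e6 * 0.001 ** 1.5, rel=1e-3)

    def test_zero_slip_gives_zero_tangential_force(self):
        sph = ContactSphereParams("foot", (0.0, 0.0), 0.02)
        f = hunt_crossley_force(sph, (0.0, 0.015), (0.0, 0.0))
        assert f[0] == 0.0

    def test_normal_force_monotone_in_static_penetration(self):
        sph = ContactSphereParams("foot", (0.0, 0.0), 0.02)
        heights = np.linspace(0.05, -0.01, 200)
        forces = [hunt_crossley_force(sph, (0.0, h), (0.0, 0.0))[1] for h in heights]
        forces = np.array(forces)
        assert np.all(forces >= 0)
        assert np.all(np.diff(forces) >= -1e-12)

    def test_contact_grf_sums_per_sphere_forces(self, model):
        q = np.zeros(model.nq)
        q[1] = 0.80  # feet penetrate slightly
        st = GeneralizedState(q, np.zeros(model.nq))
        per_sphere, per_foot, wrench = contact_grf(model, st)
        total = per_sphere.sum(axis=0)
        assert np.allclose(total, sum(per_foot.values()), atol=1e-9)
        assert np.allclose(total, wrench[:2], atol=1e-9)


class TestEnvironmentForces:
    def test_mtp_spring_linear_law(self):
        assert mtp_spring_moment(0.0, 25.0) == 0.0
        assert mtp_spring_moment(0.2, 25.0) == pytest.approx(-5.0)
        assert mtp_spring_moment(0.4, 25.0) == pytest.approx(2 * mtp_spring_moment(0.2, 25.0))

    def test_drag_quadratic_law_and_odd_symmetry(self):
        p = DragParams(1.2, 0.9, 0.45)
        assert aerodynamic_drag(0.0, p) == pytest.approx(0.0, abs=1e-9)
        assert aerodynamic_drag(5.0, p) == pytest.approx(-6.075, rel=1e-9)
        assert aerodynamic_drag(-5.0, p) == pytest.approx(6.075, rel=1e-9)

    def test_com_two_point_masses(self):
        segs = [Segment("a", 1.0, 1e-3, 0.1, (0.0, 0.0)),
                Segment("b", 1.0, 1e-3, 0.1, (2.0, 0.0))]
        joints = [Joint("j", "a", "b", (0.0, 0.0))]
        m = ModelSpec(segs, joints)
        pos, _ = com_state(m, GeneralizedState(np.zeros(4), np.zeros(4)))
        assert pos[0] == pytest.approx(1.0)

    def test_com_velocity_is_time_derivative_of_position(self, model, rng):
        q = rng.normal(0, 0.3, model.nq)
        q[1] += 1.0
        v = rng.normal(0, 1, model.nq)
        h = 1e-6
        p_plus, _ = com_state(model, GeneralizedState(q + h * v, np.zeros(model.nq)))
        p_minus, _ = com_state(model, GeneralizedState(q - h * v, np.zeros(model.nq)))
        _, vel = com_state(model, GeneralizedState(q, v))
        fd = (p_plus - p_minus) / (2 * h)
        assert np.abs(fd - vel).max() < 1e-6


class TestBatchedEvaluation:
    def test_batched_twins_match_scalar_routines(self, model, rng):
        from sprintopt.model import (
            _fk_batch,
            com_state_batch,
            inverse_dynamics_batch,
            sphere_forces_batch,
        )

        B = 6
        q = rng.normal(0, 0.3, (B, model.nq))
        q[:, 1] += 0.9
        v = rng.normal(0, 1.0, (B, model.nq))
        a = rng.normal(0, 3.0, (B, model.nq))
        idb = inverse_dynamics_batch(model, q, v, a)
        kin = _fk_batch(model, q, v)
        fb = sphere_forces_batch(model, kin)
        cb, vb = com_state_batch(model, kin)
        for b in range(B):
            st = GeneralizedState(q[b], v[b])
            assert np.allclose(idb[b], inverse_dynamics(model, q[b], v[b], a[b]), atol=1e-9)
            assert np.allclose(fb[b], sphere_forces(model, st), atol=1e-7)
            p, vv = com_state(model, st)
            assert np.allclose(cb[b], p) and np.allclose(vb[b], vv)


class TestValidation:
    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            ModelSpec([Segment("a", -1.0, 0.1, 0.1, (0, 0))], [])

    def test_rejects_unknown_contact_segment(self):
        with pytest.raises(ValueError):
            ModelSpec(
                [Segment("a", 1.0, 0.1, 0.1, (0, 0))], [],
                contact_spheres=[ContactSphereParams("nope", (0, 0), 0.02)],
            )

    def test_total_mass_matches_configuration(self, model):
        assert model.total_mass == pytest.approx(72.2, abs=1e-9)

    def test_dimension_mismatch_raises(self, model):
        st = GeneralizedState(np.zeros(model.nq), np.zeros(model.nq))
        with pytest.raises(ValueError):
            eom_residual(model, st, np.zeros(model.nq - 1), np.zeros(model.nq - 3),
                         np.zeros(2 * len(model.contact_spheres)), np.zeros(2))


class TestConfigRoundTrip:
    def test_yaml_round_trip_preserves_dynamics(self, model, rng):
        import yaml

        from sprintopt.model import model_from_dict, model_to_dict

        text = yaml.safe_dump(model_to_dict(model))
        back = model_from_dict(yaml.safe_load(text))
        assert back.dof_names == model.dof_names
        assert back.total_mass == pytest.approx(model.total_mass)
        q = rng.normal(0, 0.3, model.nq)
        v = rng.normal(0, 1, model.nq)
        a = rng.normal(0, 2, model.nq)
        assert np.allclose(inverse_dynamics(back, q, v, a),
                           inverse_dynamics(model, q, v, a), atol=1e-12)
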