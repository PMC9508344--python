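"""Data-tracking optimal control simulation.

Builds and solves the tracking problem: find states and controls of the
planar model that reproduce an experiment's kinematics, ground reaction
forces and net joint moments over a fixed horizon while satisfying the
implicit skeletal (and optionally muscle) dynamics as path constraints.

The objective is a weighted sum of squared, normalized deviations:
a tracking term (coordinates, GRF, net moments except MTP), an effort
term (activations weighted by maximal isometric force), and a control
regularization term (reserves, coordinate accelerations, muscle-state
rates). Tracked deviations are normalized by 10% of each signal's
experimental range, except the pelvis anterior-posterior translation,
which uses 0.01 m so forward progression is matched tightly.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.signal import butter, filtfilt

from . import collocation as coll
from .model import (
    GeneralizedState,
    ModelSpec,
    aerodynamic_drag,
    com_state,
    mtp_spring_torques,
)
from .muscle import (
    ActivationParams,
    HillCurves,
    MTUParams,
    hill_residual_raw,
    mtu_geometry,
)
from .timeseries import ExperimentData

logger = logging.getLogger(__name__)

__all__ = [
    "TrackingWeights",
    "NormalizationSpec",
    "PreprocessedData",
    "preprocess",
    "rmsd",
    "tracking_bounds_and_guess",
    "build_tracking_ocp",
    "run_tracking",
    "TrackingResult",
]

GRF_CONTROL_BOUND = 2500.0  # N, per component
RESERVE_BOUND = 10.0  # N m
RESERVE_BOUND_MTP = 40.0  # N m
ACTUATOR_BOUND = 6000.0  # N m, idealized torque actuators
FT_BOUNDS = (0.0, 5.0)  # normalized tendon force
FT_RATE_BOUND = 50.0  # 1/s
ACT_RATE_BOUND = 100.0  # 1/s


@dataclass
class TrackingWeights:
    """Objective weights w1..w7 (kinematics, GRF, moments, effort,
    reserves, accelerations, muscle-state rates)."""

    w1: float = 0.1
    w2: float = 0.05
    w3: float = 0.01
    w4: float = 0.01
    w5: float = 0.001
    w6: float = 0.0001
    w7: float = 0.1

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4, self.w5, self.w6, self.w7) < 0:
            raise ValueError("weights must be >= 0")


def rmsd(a, b) -> float:
    """Root-mean-square difference of two aligned series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    return float(np.sqrt(np.mean((a - b) ** 2)))


class PreprocessedData:
    """Filtered experiment plus B-spline kinematics with derivatives."""

    def __init__(self, exp: ExperimentData, q_spline, grf_spline, mom_spline):
        self.exp = exp
        self._q = q_spline
        self._v = q_spline.derivative()
        self._a = self._v.derivative()
        self._grf = grf_spline
        self._mom = mom_spline

    def q(self, t):
        return self._q(t)

    def v(self, t):
        return self._v(t)

    def a(self, t):
        return self._a(t)

    def grf(self, t):
        return self._grf(t)

    def moments(self, t):
        return self._mom(t)


def _zero_phase_lowpass(x, fs, cutoff, order):
    """Zero-phase Butterworth low-pass with dual-pass cutoff correction.

    ``order`` is the effective (overall) order; each of the two passes
    uses order/2 with the cutoff raised so the combined -3 dB point lands
    at ``cutoff``.
    """
    n_pass = max(order // 2, 1)
    corr = (2.0 ** (1.0 / n_pass) - 1.0) ** (-1.0 / (2.0 * n_pass))
    wn = corr * cutoff / (fs / 2.0)
    if wn >= 1.0:
        raise ValueError("cutoff frequency at or above Nyquist")
    b, a = butter(n_pass, wn)
    return filtfilt(b, a, x, axis=0)


def preprocess(raw: ExperimentData, cutoff: float | None = 20.0, order: int = 4) -> PreprocessedData:
    """Butterworth-filter kinematics and GRF, fit B-splines to kinematics.

    Mirrors standard biomechanics practice for measured inputs: zero-phase
    fourth-order low-pass at 20 Hz, then quintic B-splines so coordinate
    velocities and accelerations are available on any time grid. Pass
    ``cutoff=None`` for data that is already the product of such a
    pipeline (e.g. noise-free synthetic trials, which are dynamically
    consistent as generated); re-filtering consistent data perturbs the
    kinematics-to-contact-force relationship that tracking relies on.
    """
    fs = raw.sampling_rate
    if cutoff is not None and cutoff >= fs / 2.0:
        raise ValueError("cutoff frequency at or above Nyquist")
    dtg = np.diff(raw.time)
    if np.max(np.abs(dtg - dtg[0])) > 1e-6:
        raise ValueError("preprocessing requires uniform sampling")
    if cutoff is None:
        coords = raw.coords.to_numpy().copy()
        grf = raw.grf.to_numpy().copy()
    else:
        coords = _zero_phase_lowpass(raw.coords.to_numpy(), fs, cutoff, order)
        grf = _zero_phase_lowpass(raw.grf.to_numpy(), fs, cutoff, order)
    exp = ExperimentData(
        time=raw.time,
        coords=pd.DataFrame(coords, columns=raw.coords.columns),
        grf=pd.DataFrame(grf, columns=raw.grf.columns),
        moments=raw.moments.copy(),
        body_mass=raw.body_mass,
        stance_windows=dict(raw.stance_windows),
        trial_id=raw.trial_id,
        metadata=dict(raw.metadata),
    )
    q_spl = make_interp_spline(exp.time, coords, k=5)
    grf_spl = make_interp_spline(exp.time, grf, k=3)
    mom_spl = make_interp_spline(exp.time, raw.moments.to_numpy(), k=3)
    return PreprocessedData(exp, q_spl, grf_spl, mom_spl)


@dataclass
class NormalizationSpec:
    """Per-signal normalizers for the tracking objective."""

    q: np.ndarray  # per coordinate
    grf: np.ndarray  # per GRF component
    moments: np.ndarray  # per tracked internal DOF
    accel: np.ndarray  # per coordinate (u_vdot)

    def __post_init__(self):
        for name in ("q", "grf", "moments", "accel"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"normalizer {name} must be positive")

    @classmethod
    def from_experiment(cls, prep: PreprocessedData, model: ModelSpec,
                        pelvis_ap_norm: float = 0.01, fraction: float = 0.10):
        t = prep.exp.time
        qs = prep.q(t)
        accs = prep.a(t)
        grfs = prep.exp.grf.to_numpy()
        moms = prep.exp.moments.to_numpy()

        def rng(x, floor):
            # fraction of the experimental range, floored so a flat signal
            # cannot produce a near-singular normalizer
            r = np.ptp(x, axis=0)
            return np.maximum(fraction * r, floor)

        qn = rng(qs, 0.01)  # rad / m
        qn[model.dof_index("base_x")] = pelvis_ap_norm
        return cls(q=qn, grf=rng(grfs, 5.0), moments=rng(moms, 2.0),
                   accel=rng(accs, 10.0))


def tracking_bounds_and_guess(prep: PreprocessedData, model: ModelSpec,
                              mesh: coll.Mesh, muscles: list[MTUParams] | None = None):
    """State/control bounds and initial guess from the experimental splines.

    Kinematic bounds extend 25% of each signal's range beyond its extrema
    (fixed fallback margin for degenerate signals); reserves are bounded
    at +-10 N m (+-40 at MTP joints), GRF controls at +-2500 N; muscle
    states and rates use the conventional prior bounds. The initial guess
    takes kinematic states and accelerations from the splines, upper-limb
    actuator torques from the experimental net moments, and zero reserves
    and GRF controls.
    """
    t = prep.exp.time
    qs, vs, accs = prep.q(t), prep.v(t), prep.a(t)

    def expand(x):
        lo, hi = x.min(axis=0), x.max(axis=0)
        r = hi - lo
        r = np.where(r < 1e-9, 1.0, r)
        return lo - 0.25 * r, hi + 0.25 * r

    q_lo, q_hi = expand(qs)
    v_lo, v_hi = expand(vs)
    a_lo, a_hi = expand(accs)
    # robust cap on the acceleration-control bounds: short-lived spikes in
    # the experimental accelerations would otherwise blow up the variable
    # scaling and the conditioning of the dynamics rows
    a_cap = 4.0 * np.percentile(np.abs(accs), 98, axis=0) + 10.0
    a_lo = np.maximum(a_lo, -a_cap)
    a_hi = np.minimum(a_hi, a_cap)
    layout = _Layout(model, muscles)
    nx, nu = layout.nx, layout.nu
    x_lb = np.concatenate([q_lo, v_lo] + ([np.full(layout.nm, FT_BOUNDS[0]),
                                           np.zeros(layout.nm)] if layout.nm else []))
    x_ub = np.concatenate([q_hi, v_hi] + ([np.full(layout.nm, FT_BOUNDS[1]),
                                           np.ones(layout.nm)] if layout.nm else []))
    u_lb = np.empty(nu)
    u_ub = np.empty(nu)
    u_lb[layout.sl_vdot] = a_lo
    u_ub[layout.sl_vdot] = a_hi
    u_lb[layout.sl_act] = -ACTUATOR_BOUND
    u_ub[layout.sl_act] = ACTUATOR_BOUND
    res_b = np.array([
        RESERVE_BOUND_MTP if d in model.mtp_joints else RESERVE_BOUND
        for d in model.internal_dofs
    ])
    u_lb[layout.sl_res] = -res_b
    u_ub[layout.sl_res] = res_b
    u_lb[layout.sl_grf] = -GRF_CONTROL_BOUND
    u_ub[layout.sl_grf] = GRF_CONTROL_BOUND
    if layout.nm:
        u_lb[layout.sl_ftdot] = -FT_RATE_BOUND
        u_ub[layout.sl_ftdot] = FT_RATE_BOUND
        u_lb[layout.sl_adot] = -ACT_RATE_BOUND
        u_ub[layout.sl_adot] = ACT_RATE_BOUND

    # initial guess on the mesh
    starts, colls = mesh.normalized_times()
    tf = mesh.tf_bounds[0]
    states = np.zeros((mesh.n_intervals, mesh.d + 1, nx))
    controls = np.zeros((mesh.n_intervals, nu))
    mom_fn = prep.moments
    curves = HillCurves() if layout.nm else None
    a_init = 0.1

    def ft_equilibrium(qv, vv, p):
        """Tendon-force guess: Hill equilibrium root at low activation."""
        from scipy.optimize import brentq

        qd = {d: qv[model.dof_index(d)] for d in p.dofs}
        vd = {d: vv[model.dof_index(d)] for d in p.dofs}
        try:
            return brentq(
                lambda ft: hill_residual_raw(qd, vd, ft, a_init, p, curves),
                1e-6, 3.0, xtol=1e-6,
            )
        except ValueError:
            return 0.2

    for i in range(mesh.n_intervals):
        pts = np.concatenate([[starts[i]], colls[i]]) * tf
        for k, tp in enumerate(pts):
            states[i, k, layout.sl_q] = prep.q(tp)
            states[i, k, layout.sl_v] = prep.v(tp)
            if layout.nm:
                for m_i, p in enumerate(layout.muscles):
                    states[i, k, layout.sl_ft.start + m_i] = ft_equilibrium(
                        prep.q(tp), prep.v(tp), p)
                states[i, k, layout.sl_a] = a_init
        t0 = starts[i] * tf
        controls[i, layout.sl_vdot] = prep.a(t0)
        tau_exp = mom_fn(t0)
        spring = mtp_spring_torques(model, prep.q(t0))
        controls[i, layout.sl_act] = np.clip(
            (tau_exp - spring) * layout.torque_mask, -ACTUATOR_BOUND, ACTUATOR_BOUND
        )
    states = np.clip(states, x_lb, x_ub)
    controls = np.clip(controls, u_lb, u_ub)
    return (x_lb, x_ub, u_lb, u_ub), (states, controls, tf)


class _Layout:
    """Decision-variable layout for the model (+ optional muscle set)."""

    def __init__(self, model: ModelSpec, muscles: list[MTUParams] | None):
        self.model = model
        self.muscles = muscles or []
        self.nm = len(self.muscles)
        nq = model.nq
        n_int = nq - 3
        nfeet = len(model.feet)
        self.nq, self.n_int, self.nfeet = nq, n_int, nfeet
        self.nx = 2 * nq + 2 * self.nm
        self.sl_q = slice(0, nq)
        self.sl_v = slice(nq, 2 * nq)
        self.sl_ft = slice(2 * nq, 2 * nq + self.nm)
        self.sl_a = slice(2 * nq + self.nm, 2 * nq + 2 * self.nm)
        # controls: u_vdot | u_act | u_res | u_grf | u_ftdot | u_adot
        self.sl_vdot = slice(0, nq)
        self.sl_act = slice(nq, nq + n_int)
        self.sl_res = slice(nq + n_int, nq + 2 * n_int)
        self.sl_grf = slice(nq + 2 * n_int, nq + 2 * n_int + 2 * nfeet)
        off = nq + 2 * n_int + 2 * nfeet
        self.sl_ftdot = slice(off, off + self.nm)
        self.sl_adot = slice(off + self.nm, off + 2 * self.nm)
        self.nu = off + 2 * self.nm
        # torque actuators act on DOFs mapped "torque"; muscle-driven DOFs
        # rely on MTUs + reserves
        self.torque_mask = np.array(
            [1.0 if model.actuator_map[d] == "torque" else 0.0 for d in model.internal_dofs]
        )
        # linear dynamics: qdot = v, vdot = u_vdot, ftdot/adot = controls
        self.A_x = np.zeros((self.nx, self.nx))
        self.A_x[self.sl_q, self.sl_v] = np.eye(nq)
        self.A_u = np.zeros((self.nx, self.nu))
        self.A_u[self.sl_v, self.sl_vdot] = np.eye(nq)
        if self.nm:
            self.A_u[self.sl_ft, self.sl_ftdot] = np.eye(self.nm)
            self.A_u[self.sl_a, self.sl_adot] = np.eye(self.nm)

    def net_moments(self, x, u):
        """Simulated net joint moments (actuators + reserves + springs +
        muscle contributions) per internal DOF."""
        q = x[self.sl_q]
        tau = u[self.sl_act] * self.torque_mask + u[self.sl_res]
        tau = tau + mtp_spring_torques(self.model, q)
        if self.nm:
            qd = {d: q[self.model.dof_index(d)] for d in self.model.internal_dofs}
            ft = x[self.sl_ft]
            for m_i, p in enumerate(self.muscles):
                _, _, arms = mtu_geometry(qd, p)
                for dof, r in arms.items():
                    j = self.model.internal_dofs.index(dof)
                    tau[j] = tau[j] + ft[m_i] * p.fmax * r
        return tau


def _foot_grf_sums(model: ModelSpec, per_sphere):
    """Per-foot (AP, vertical) sums in the order of ``model.feet``."""
    out = []
    for f in model.feet:
        s = 0.0 * per_sphere[0]
        for k, sph in enumerate(model.contact_spheres):
            if sph.segment == f:
                s = s + per_sphere[k]
        out.append(s)
    return np.concatenate(out)


def build_tracking_ocp(
    prep: PreprocessedData,
    model: ModelSpec,
    mesh: coll.Mesh,
    weights: TrackingWeights | None = None,
    norms: NormalizationSpec | None = None,
    muscles: list[MTUParams] | None = None,
    curves: HillCurves | None = None,
    act_params: ActivationParams | None = None,
) -> tuple[coll.OCPDefinition, tuple]:
    """Assemble the tracking OCP and its initial guess."""
    weights = weights or TrackingWeights()
    norms = norms or NormalizationSpec.from_experiment(prep, model)
    layout = _Layout(model, muscles)
    curves = curves or HillCurves()
    act_params = act_params or ActivationParams()
    tf = prep.exp.duration
    mesh.t_final = tf
    (x_lb, x_ub, u_lb, u_ub), guess = tracking_bounds_and_guess(prep, model, mesh, muscles)

    from .model import hunt_crossley_force, sphere_forces

    nq = model.nq
    n_path = nq + 2 * layout.nfeet + 2 * layout.nm
    # tracked moments exclude the MTP joints
    tracked_idx = [i for i, d in enumerate(model.internal_dofs) if d not in model.mtp_joints]
    mtp_excluded = [d for d in model.internal_dofs if d in model.mtp_joints]
    if mtp_excluded:
        logger.info("moment tracking excludes MTP joints: %s", mtp_excluded)

    def path(x, u, sigma, tf_val):
        q = x[layout.sl_q]
        v = x[layout.sl_v]
        st = GeneralizedState(q, v)
        per_sphere = sphere_forces(model, st)
        _, com_v = com_state(model, st)
        drag = np.array([aerodynamic_drag(com_v[0], model.drag), 0.0 * com_v[0]])
        tau = layout.net_moments(x, u)
        from .model import eom_residual

        eom = eom_residual(model, st, u[layout.sl_vdot], tau, per_sphere.reshape(-1), drag)
        grf_cons = _foot_grf_sums(model, per_sphere) - u[layout.sl_grf]
        parts = [eom, grf_cons]
        if layout.nm:
            qd = {d: q[model.dof_index(d)] for d in model.internal_dofs}
            vd = {d: v[model.dof_index(d)] for d in model.internal_dofs}
            hill = []
            for m_i, p in enumerate(layout.muscles):
                hill.append(
                    hill_residual_raw(
                        qd, vd, x[layout.sl_ft][m_i], x[layout.sl_a][m_i],
                        p, curves, u[layout.sl_ftdot][m_i],
                    )
                )
            a_states = x[layout.sl_a]
            u_adot = u[layout.sl_adot]
            g_lower = u_adot + a_states / act_params.tau_deact
            g_upper = u_adot + a_states / act_params.tau_act - 1.0 / act_params.tau_act
            parts += [np.asarray(hill), g_lower, g_upper]
        return np.concatenate(parts)

    from .model import (
        _fk_batch,
        com_state_batch,
        external_generalized_batch,
        inverse_dynamics_batch,
        sphere_forces_batch,
    )

    def _net_moments_batch(X, U):
        q = X[:, layout.sl_q]
        tau = U[:, layout.sl_act] * layout.torque_mask + U[:, layout.sl_res]
        tau = tau.astype(np.result_type(X, U))
        for name in model.mtp_joints:
            j = model.internal_dofs.index(name)
            tau[:, j] = tau[:, j] - model.mtp_spring_stiffness * (
                q[:, model.dof_index(name)] - model.mtp_neutral_angle
            )
        if layout.nm:
            qd = {d: q[:, model.dof_index(d)] for d in model.internal_dofs}
            ft = X[:, layout.sl_ft]
            for m_i, p in enumerate(layout.muscles):
                _, _, arms = mtu_geometry(qd, p)
                for dof, r in arms.items():
                    j = model.internal_dofs.index(dof)
                    tau[:, j] = tau[:, j] + ft[:, m_i] * p.fmax * r
        return tau

    feet_sphere_idx = {
        f: [k for k, sph in enumerate(model.contact_spheres) if sph.segment == f]
        for f in model.feet
    }

    def path_batch(X, U, sigma, TF):
        q = X[:, layout.sl_q]
        v = X[:, layout.sl_v]
        kin = _fk_batch(model, q, v)
        per_sphere = sphere_forces_batch(model, kin)
        _, com_v = com_state_batch(model, kin)
        dragx = aerodynamic_drag(com_v[:, 0], model.drag)
        drag = np.stack([dragx, 0.0 * dragx], axis=-1)
        ID = inverse_dynamics_batch(model, q, v, U[:, layout.sl_vdot])
        ext = external_generalized_batch(model, kin, per_sphere, drag)
        eom = ID - ext
        eom[:, 3:] -= _net_moments_batch(X, U)
        sums = [per_sphere[:, feet_sphere_idx[f], :].sum(axis=1) for f in model.feet]
        grf_cons = np.concatenate(sums, axis=1) - U[:, layout.sl_grf]
        parts = [eom, grf_cons]
        if layout.nm:
            qd = {d: q[:, model.dof_index(d)] for d in model.internal_dofs}
            vd = {d: v[:, model.dof_index(d)] for d in model.internal_dofs}
            hill = np.stack(
                [
                    hill_residual_raw(
                        qd, vd, X[:, layout.sl_ft][:, m_i], X[:, layout.sl_a][:, m_i],
                        p, curves, U[:, layout.sl_ftdot][:, m_i],
                    )
                    for m_i, p in enumerate(layout.muscles)
                ],
                axis=1,
            )
            a_states = X[:, layout.sl_a]
            u_adot = U[:, layout.sl_adot]
            parts += [
                hill,
                u_adot + a_states / act_params.tau_deact,
                u_adot + a_states / act_params.tau_act - 1.0 / act_params.tau_act,
            ]
        return np.concatenate(parts, axis=1)

    path_lb = np.concatenate([
        np.zeros(nq + 2 * layout.nfeet),
        *( [np.zeros(layout.nm), np.zeros(layout.nm), np.full(layout.nm, -np.inf)]
           if layout.nm else [] ),
    ])
    path_ub = np.concatenate([
        np.zeros(nq + 2 * layout.nfeet),
        *( [np.zeros(layout.nm), np.full(layout.nm, np.inf), np.zeros(layout.nm)]
           if layout.nm else [] ),
    ])
    # row scaling: dynamics rows by a characteristic force/moment, GRF rows
    # by a body-weight scale
    bw = model.total_mass * model.gravity
    path_scale = np.concatenate([
        np.full(nq, 1000.0),
        np.full(2 * layout.nfeet, 2.0 * bw),
        *( [np.full(layout.nm, 0.1), np.full(2 * layout.nm, 10.0)] if layout.nm else [] ),
    ])

    w = weights
    fmax = np.array([p.fmax for p in layout.muscles]) if layout.nm else np.zeros(0)
    fmax_w = np.sqrt(w.w4 * fmax / fmax.sum()) if layout.nm else fmax
    res_b = np.array([
        RESERVE_BOUND_MTP if d in model.mtp_joints else RESERVE_BOUND
        for d in model.internal_dofs
    ])

    n_track_q = nq
    n_track_grf = 2 * layout.nfeet
    n_track_mom = len(tracked_idx)

    def quad_residuals(x, u, sigma, tf_val):
        tphys = sigma * tf_val
        r_q = np.sqrt(w.w1) * (prep.q(tphys) - x[layout.sl_q]) / norms.q
        r_grf = np.sqrt(w.w2) * (prep.grf(tphys) - u[layout.sl_grf]) / norms.grf
        tau = layout.net_moments(x, u)
        r_mom = np.sqrt(w.w3) * (
            (prep.moments(tphys) - tau)[tracked_idx] / norms.moments[tracked_idx]
        )
        r_res = np.sqrt(w.w5) * u[layout.sl_res] / res_b
        r_acc = np.sqrt(w.w6) * u[layout.sl_vdot] / norms.accel
        parts = [r_q, r_grf, r_mom, r_res, r_acc]
        if layout.nm:
            parts.append(fmax_w * x[layout.sl_a])
            parts.append(np.sqrt(w.w7) * u[layout.sl_ftdot] / FT_RATE_BOUND)
            parts.append(np.sqrt(w.w7) * u[layout.sl_adot] / ACT_RATE_BOUND)
        return np.concatenate(parts)

    def quad_batch(X, U, sigma, TF):
        tphys = np.real(sigma) * np.real(TF)
        r_q = np.sqrt(w.w1) * (prep.q(tphys) - X[:, layout.sl_q]) / norms.q
        r_grf = np.sqrt(w.w2) * (prep.grf(tphys) - U[:, layout.sl_grf]) / norms.grf
        tau = _net_moments_batch(X, U)
        r_mom = np.sqrt(w.w3) * (
            (prep.moments(tphys) - tau)[:, tracked_idx] / norms.moments[tracked_idx]
        )
        r_res = np.sqrt(w.w5) * U[:, layout.sl_res] / res_b
        r_acc = np.sqrt(w.w6) * U[:, layout.sl_vdot] / norms.accel
        parts = [r_q, r_grf, r_mom, r_res, r_acc]
        if layout.nm:
            parts.append(fmax_w * X[:, layout.sl_a])
            parts.append(np.sqrt(w.w7) * U[:, layout.sl_ftdot] / FT_RATE_BOUND)
            parts.append(np.sqrt(w.w7) * U[:, layout.sl_adot] / ACT_RATE_BOUND)
        return np.concatenate(parts, axis=1)

    off = 0
    term_slices = {}
    for name, size in (
        ("tracking_q", n_track_q),
        ("tracking_grf", n_track_grf),
        ("tracking_moments", n_track_mom),
        ("control_reserves", layout.n_int),
        ("control_accelerations", nq),
    ):
        term_slices[name] = slice(off, off + size)
        off += size
    if layout.nm:
        term_slices["effort"] = slice(off, off + layout.nm)
        off += layout.nm
        term_slices["control_muscle_rates"] = slice(off, off + 2 * layout.nm)
        off += 2 * layout.nm

    ocp = coll.OCPDefinition(
        nx=layout.nx,
        nu=layout.nu,
        A_x=layout.A_x,
        A_u=layout.A_u,
        x_lb=x_lb,
        x_ub=x_ub,
        u_lb=u_lb,
        u_ub=u_ub,
        path=path,
        path_batch=path_batch,
        path_lb=path_lb,
        path_ub=path_ub,
        path_scale=path_scale,
        quad_residuals=quad_residuals,
        quad_batch=quad_batch,
        n_quad=off,
        term_slices=term_slices,
    )
    return ocp, guess, layout, norms


@dataclass
class TrackingResult:
    solution: coll.OCPSolution
    layout: _Layout
    norms: NormalizationSpec
    prep: PreprocessedData | None = None
    rmsd_q: dict = field(default_factory=dict)
    rmsd_grf_bw: dict = field(default_factory=dict)
    rmsd_moments: dict = field(default_factory=dict)
    solve_seconds: float = 0.0

    def moments_series(self, times):
        """Net joint moments of the solution at given times."""
        xs = self.solution.interpolate(times)
        us = self.solution.control_at(times)
        return np.array([
            np.real(self.layout.net_moments(x, u)) for x, u in zip(xs, us)
        ])

    def summary(self) -> dict:
        s = self.solution
        return {
            "status": s.status,
            "success": s.success,
            "objective": s.objective,
            "breakdown": {k: float(v) for k, v in s.breakdown.items()},
            "iterations": s.n_iter,
            "constraint_violation": s.constr_violation,
            "t_final": s.t_final,
            "rmsd_q": self.rmsd_q,
            "rmsd_grf_bw": self.rmsd_grf_bw,
            "rmsd_moments": self.rmsd_moments,
            "solve_seconds": self.solve_seconds,
        }


def run_tracking(
    exp: ExperimentData,
    model: ModelSpec,
    n_intervals: int = 50,
    d: int = 3,
    weights: TrackingWeights | None = None,
    muscles: list[MTUParams] | None = None,
    tol: float = 1e-3,
    maxiter: int = 400,
    cutoff: float | None = 20.0,
) -> TrackingResult:
    """Preprocess, build, and solve the data-tracking simulation."""
    prep = preprocess(exp, cutoff=cutoff)
    mesh = coll.Mesh(n_intervals, d, prep.exp.duration)
    ocp, guess, layout, norms = build_tracking_ocp(prep, model, mesh, weights, muscles=muscles)
    tr = coll.transcribe(ocp, mesh)
    t0 = time.time()
    sol = coll.solve(tr, guess, tol=tol, maxiter=maxiter)
    dt_solve = time.time() - t0
    logger.info(
        "tracking solve: status %s (%s) in %.1f s, %d iterations, objective %.4f",
        sol.status, sol.message, dt_solve, sol.n_iter, sol.objective,
    )
    result = TrackingResult(sol, layout, norms, prep=prep, solve_seconds=dt_solve)

    # RMSDs against the (filtered) experimental series
    t = prep.exp.time
    xs = sol.interpolate(t)
    us = sol.control_at(t)
    bw = exp.body_mass * model.gravity
    for j, name in enumerate(model.dof_names):
        result.rmsd_q[name] = rmsd(prep.q(t)[:, j], xs[:, j])
    grf_cols = list(prep.exp.grf.columns)
    for j, name in enumerate(grf_cols):
        result.rmsd_grf_bw[name] = rmsd(prep.grf(t)[:, j], us[:, layout.sl_grf][:, j]) / bw
    sim_mom = result.moments_series(t)
    for j, name in enumerate(model.internal_dofs):
        result.rmsd_moments[name] = rmsd(prep.moments(t)[:, j], sim_mom[:, j])
    return result
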