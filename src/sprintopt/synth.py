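"""Synthetic two-step accelerative-sprint experiments.

Generates dynamically consistent kinematics / ground-reaction-force / net
joint moment triplets for the planar model over two consecutive stance
phases (right then left) with an intervening flight phase, emulating the
structure of an early-acceleration sprint trial: forward-accelerating
CoM, forward trunk lean, forefoot-only contact with heel rise into
take-off, touchdown slightly ahead of the CoM, and ground reaction forces
with the braking-then-propulsive shape of accelerative sprinting.

The construction works backwards from the external forces:

1. The whole-body CoM trajectory is prescribed: smooth force-shaped
   velocity profiles during stance, exactly ballistic (and drag-decelerated)
   arcs during flight. The required external contact force during each
   stance follows from Newton's law and is therefore smooth and exactly
   zero in flight.
2. The stance-foot toe-sphere trajectory is solved from the *inverse* of
   the smooth Hunt-Crossley law: penetration depth from the required
   normal force and slip velocity from the required tangential/normal
   ratio through the regularized friction law. Swing-foot paths and foot
   pitch profiles are scripted splines; contact is forefoot-only by
   construction (the heel sphere keeps ground clearance).
3. Internal joint angles follow by planar two-link inverse kinematics
   against the pelvis, whose translation is fixed-point-adjusted so the
   realized whole-body CoM matches the prescribed one, and whose pitch is
   integrated from the unactuated base-rotation row of the equation of
   motion (with a shooting pass on the initial pitch rate).
4. Net joint moments at the internal DOFs are read off the equation-of-
   motion residual of the final splined trajectory, making the
   (q, GRF, tau) triplet consistent to spline tolerance; the worst
   base-row residual is reported as a diagnostic and generation fails if
   it exceeds the configured threshold.

Optional seeded Gaussian noise on coordinates and GRF emulates measurement
error ahead of the downstream Butterworth + B-spline preprocessing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import make_interp_spline

from .model import (
    GeneralizedState,
    ModelSpec,
    _perp,
    _rot,
    aerodynamic_drag,
    com_state,
    contact_grf,
    default_model,
    eom_residual,
    forward_kinematics,
    hunt_crossley_force,
    inverse_dynamics,
)
from .outcomes import detect_stance
from .timeseries import ExperimentData

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "generate_reference_kinematics", "derive_consistent_kinetics",
           "add_noise_and_package", "generate_experiment"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic two-step trial."""

    seed: int = 0
    body_mass: float = 72.2  # kg
    stature: float = 1.79  # m
    horizon: float = 0.436  # s, right touchdown to left take-off
    stance_duration_r: float = 0.185  # s
    stance_duration_l: float = 0.165  # s
    v0: float = 4.5  # m/s, initial horizontal CoM velocity
    delta_v: float = 1.0  # m/s, horizontal CoM velocity gain over the horizon
    vy0: float = -0.25  # m/s, vertical CoM velocity at right touchdown
    vy_takeoff: float = 0.45  # m/s, vertical CoM velocity at right take-off
    vy_end: float = 0.35  # m/s, vertical CoM velocity at the horizon end
    com_height: float = 0.87  # m, CoM height at t = 0 (crouched acceleration)
    touchdown_lead: float = 0.09  # m, toe ahead of CoM at touchdown
    braking_impulse: float = 1.5  # N s magnitude of the per-stance braking dip
    prop_share_r: float = 0.53  # right-stance share of the velocity gain
    sampling_rate: float = 250.0  # Hz
    noise_std_q: float = 0.0  # rad, coordinate noise (angles)
    noise_std_trans: float = 0.002  # m, translation noise when noise_std_q > 0
    noise_std_grf: float = 0.0  # N
    base_residual_threshold: float = 5.0  # N / N m
    sweeps: int = 3  # CoM-matching fixed-point sweeps
    plan_jitter: float = 0.02  # relative seeded jitter of swing waypoints

    def __post_init__(self):
        gap = self.horizon - self.stance_duration_r - self.stance_duration_l
        if gap <= 0.01:
            raise ValueError("stance windows must leave a flight gap inside the horizon")
        if min(self.noise_std_q, self.noise_std_grf, self.noise_std_trans) < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def stance_r(self) -> tuple[float, float]:
        return (0.0, self.stance_duration_r)

    @property
    def stance_l(self) -> tuple[float, float]:
        return (self.horizon - self.stance_duration_l, self.horizon)


# ----------------------------------------------------------------------
# CoM prescription


def _stance_shape(s):
    """Half-sine force pulse on [0, 1]: the canonical spring-mass running
    ground-reaction profile (zero at touchdown/take-off, single broad
    peak)."""
    return np.sin(np.pi * np.clip(s, 0.0, 1.0))


def _brake_shape(s):
    """Early-stance braking dip shape (support on s < 0.3)."""
    s = np.clip(s, 0.0, 1.0)
    return np.where(s < 0.3, np.sin(np.pi * s / 0.3) ** 2, 0.0)


class _ComPlan:
    """Prescribed whole-body CoM trajectory and required contact force."""

    def __init__(self, cfg: SynthConfig, model: ModelSpec, times: np.ndarray):
        self.cfg = cfg
        self.times = times
        m = cfg.body_mass
        g = model.gravity
        tr, tl = cfg.stance_r, cfg.stance_l
        sr = (times - tr[0]) / (tr[1] - tr[0])
        sl = (times - tl[0]) / (tl[1] - tl[0])
        in_r = (times >= tr[0]) & (times <= tr[1])
        in_l = (times >= tl[0]) & (times <= tl[1])

        # --- horizontal: net CoM acceleration profile -----------------
        dt = times[1] - times[0]
        shp_r = np.where(in_r, _stance_shape(sr), 0.0)
        shp_l = np.where(in_l, _stance_shape(sl), 0.0)
        brk_r = np.where(in_r, _brake_shape(sr), 0.0)
        brk_l = np.where(in_l, _brake_shape(sl), 0.0)
        a_brk = cfg.braking_impulse / m / np.trapezoid(brk_r, times)
        gain_r = cfg.prop_share_r * cfg.delta_v
        gain_l = (1.0 - cfg.prop_share_r) * cfg.delta_v
        # flight/drag deceleration; integrate vx forward with drag coupling
        vx = np.empty_like(times)
        vx[0] = cfg.v0
        A_r = (gain_r + a_brk * np.trapezoid(brk_r, times)) / np.trapezoid(shp_r, times)
        A_l = (gain_l + a_brk * np.trapezoid(brk_l, times)) / np.trapezoid(shp_l, times)
        ax = A_r * shp_r + A_l * shp_l - a_brk * (brk_r + brk_l)
        drag = np.empty_like(times)
        for i in range(len(times)):
            drag[i] = aerodynamic_drag(vx[i], model.drag)
            if i + 1 < len(times):
                stance = in_r[i] or in_l[i]
                acc = ax[i] + (0.0 if stance else drag[i] / m)
                vx[i + 1] = vx[i] + acc * dt
        self.vx = vx
        self.ax = np.gradient(vx, times)
        self.cx = cumulative_trapezoid(vx, times, initial=0.0)
        self.drag = drag

        # --- vertical -------------------------------------------------
        vy = np.empty_like(times)
        ay = np.full_like(times, -g)
        for window, s, mask, v_in, v_out in (
            (tr, sr, in_r, cfg.vy0, cfg.vy_takeoff),
            (tl, sl, in_l, cfg.vy0 - 0.0, cfg.vy_end),
        ):
            tau = window[1] - window[0]
            if window is tl:
                # landing velocity from the ballistic flight
                v_in = cfg.vy_takeoff - g * (tl[0] - tr[1])
            shape = _stance_shape(s) * mask
            B = (v_out - v_in + g * tau) / np.trapezoid(shape, times)
            ay = ay + B * shape
        vy = cfg.vy0 + cumulative_trapezoid(ay, times, initial=0.0)
        self.vy = vy
        self.ay = ay
        self.cy = cfg.com_height + cumulative_trapezoid(vy, times, initial=0.0)

        # required contact force (zero in flight by construction)
        self.freq_x = np.where(in_r | in_l, m * self.ax - drag, 0.0)
        self.freq_y = np.where(in_r | in_l, m * (ay + g), 0.0)
        self.in_r, self.in_l, self.sr, self.sl = in_r, in_l, sr, sl


# ----------------------------------------------------------------------
# stance contact inversion and foot paths


_PITCH_KNOTS = np.array([0.0, 0.25, 0.5, 0.75, 0.92, 1.0])
_PITCH_VALS = np.array([-0.09, -0.07, -0.28, -0.85, -1.50, -1.75])


def _invert_contact(model: ModelSpec, cfg: SynthConfig, fx, fy, s_grid, times, toe_x0):
    """Toe-sphere path realizing the required stance force.

    Inverts the smooth Hunt-Crossley law pointwise: penetration from the
    normal force (with a few damping-term iterations) and slip velocity
    from the regularized friction law.
    """
    foot = "foot_r"
    sph = [c for c in model.contact_spheres if c.segment == foot][-1]
    k, d, mu, vs = sph.stiffness, sph.dissipation, sph.friction, sph.velocity_smoothing
    scale = sph.penetration_smoothing
    # The smooth positive-part of the contact law is not inverted: using
    # the required pen_hat directly as the penetration keeps the path as
    # smooth as the force shape (the resulting force deficit is a couple
    # of newtons right at the stance edges and is absorbed by the base
    # solve). The force shape vanishes like sin(pi s)^1.5, so pen is
    # linear in time near touchdown/take-off.
    bracket = np.ones_like(fy)
    for _ in range(4):
        pen = (np.maximum(fy, 0.0) / (k * bracket)) ** (2.0 / 3.0)
        pen_rate = np.gradient(pen, times)
        bracket = np.maximum(1.0 + d * pen_rate, 0.25)
    fn = k * pen**1.5 * bracket
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(fn > 5.0, -fx / (mu * np.maximum(fn, 5.0)), 0.0)
    alpha = np.clip(alpha, -0.95, 0.95)
    v_slip = vs * np.arctanh(alpha)
    toe_x = toe_x0 + cumulative_trapezoid(v_slip, times, initial=0.0)
    toe_y = sph.radius - pen
    return toe_x, toe_y, fn


class _FootPlan:
    """Stance toe-sphere path (absolute) and global foot pitch for one foot.

    The stance path realizes the prescribed contact force through the
    inverse Hunt-Crossley law; the foot pitch is a scripted profile over
    the whole horizon (heel-up forefoot strike rolling into strong
    plantarflexion at take-off, dorsiflexion recovery during swing).
    """

    def __init__(self, model, cfg, plan: _ComPlan, foot: str, rng):
        self.foot = foot
        cfgj = lambda s=1.0: 1.0 + cfg.plan_jitter * s * rng.uniform(-1, 1)
        times = plan.times
        self.window = cfg.stance_r if foot == "foot_r" else cfg.stance_l
        mask = plan.in_r if foot == "foot_r" else plan.in_l
        s = plan.sr if foot == "foot_r" else plan.sl
        i_td = int(np.searchsorted(times, self.window[0]))
        toe_x0 = plan.cx[i_td] + cfg.touchdown_lead * (
            1.0 if foot == "foot_r" else cfgj(0.5)
        )
        fx = np.where(mask, plan.freq_x, 0.0)
        fy = np.where(mask, plan.freq_y, 0.0)
        tx, ty, _ = _invert_contact(
            model, cfg, fx[mask], fy[mask], s[mask], times[mask], toe_x0
        )
        self.toe_x = make_interp_spline(times[mask], tx, k=3)
        self.toe_y = make_interp_spline(times[mask], ty, k=3)

        # pitch over the whole horizon: stance profile + swing recovery
        t0, t1 = self.window
        T = cfg.horizon
        pk = list(t0 + _PITCH_KNOTS * (t1 - t0))
        pv = list(_PITCH_VALS)
        if t1 < T - 1e-9:  # swing after stance (right foot)
            pk += [t1 + 0.08, min(t1 + 0.16, T - 0.01), T]
            pv += [-0.9, -0.35, -0.12]
        if t0 > 1e-9:  # swing before stance (left foot)
            pk = [0.0, 0.5 * t0, t0 - 0.02] + pk
            pv = [-0.40, -0.22, -0.10] + pv
        self.pitch = make_interp_spline(pk, pv, k=3)
        sph = [c for c in model.contact_spheres if c.segment == foot][-1]
        self._loc = np.asarray(sph.location)
        # horizontal re-anchoring offset (contact forces are invariant to
        # horizontal translation, so this is free to set after the fact)
        self.x_offset = 0.0
        # stance membership extends past the horizon ends so that ghost
        # evaluations just outside [0, T] stay on the correct branch
        self._lo = -np.inf if self.window[0] <= 1e-9 else self.window[0]
        self._hi = np.inf if self.window[1] >= cfg.horizon - 1e-9 else self.window[1]

    def in_stance(self, t):
        return self._lo - 1e-12 <= t <= self._hi + 1e-12

    def ankle(self, t):
        """Stance ankle (foot-frame origin) position at time ``t``."""
        ph = self.pitch(t)
        c, s = np.cos(ph), np.sin(ph)
        ox = self.toe_x(t) + self.x_offset - (c * self._loc[0] - s * self._loc[1])
        oy = self.toe_y(t) - (s * self._loc[0] + c * self._loc[1])
        return np.array([ox, oy])


# ----------------------------------------------------------------------
# inverse kinematics


def _leg_geometry(model: ModelSpec, side: str):
    names = [j.name for j in model.joints]
    l1 = abs(model.joints[names.index(f"knee_{side}")].location[1])
    l2 = abs(model.joints[names.index(f"ankle_{side}")].location[1])
    hip_anchor = np.asarray(model.joints[names.index(f"hip_{side}")].location)
    return l1, l2, hip_anchor


def _leg_ik(l1, l2, hip, ankle):
    """Planar two-link IK: (hip angle rel. vertical, knee angle).

    The hip-ankle distance saturates smoothly just below full extension
    (softplus, ~4 mm width) so the map stays C1 for the Newton solves that
    drive the generator; the returned flag marks saturated calls.
    """
    from ._smooth import softplus

    d = np.asarray(ankle) - np.asarray(hip)
    r = np.hypot(d[0], d[1])
    L = l1 + l2
    width = 0.004 * L
    r_eff = L - width - softplus(L - width - r, width)
    clamped = r > L - 3 * width
    r_eff = max(r_eff, 0.2 * L)
    cos_k = np.clip((r_eff * r_eff - l1 * l1 - l2 * l2) / (2 * l1 * l2), -1.0, 1.0)
    qk = -np.arccos(cos_k)
    z = complex(d[0], d[1])
    w = l1 + l2 * np.exp(1j * qk)
    theta_t = np.angle(1j * z) - np.angle(w)
    return theta_t, qk, clamped


class _Skeleton:
    """IK of all internal DOFs given base pose and foot/trunk plans.

    Stance ankles follow the absolute contact-derived paths; swing ankles
    follow hip-relative polar splines (distance r, inclination gamma from
    straight down), which keeps them reachable by construction. The swing
    splines are rebuilt each sweep with boundary values and rates matched
    to the stance geometry.  ``trunk_offset`` is an additive correction to
    the planned absolute trunk angle: it is the variable integrated from
    the unactuated base-rotation row (the trunk is the only segment with
    enough rotational inertia to absorb the external angular impulse while
    the feet and CoM follow their prescriptions).
    """

    def __init__(self, model: ModelSpec, foot_plans, trunk_spline):
        self.model = model
        self.foot_plans = foot_plans
        self.trunk = trunk_spline
        self.geom = {s: _leg_geometry(model, s) for s in ("r", "l")}
        self.swing: dict[str, tuple] = {}
        self.n_clamped = 0

    def _hip(self, side, t, base):
        _, _, anchor = self.geom[side]
        return np.array([base[0], base[1]]) + _rot(base[2]) @ anchor

    _FADE = 0.05  # s, stance-to-nominal blending time into the swing

    def build_swing(self, horizon):
        """Build the nominal hip-relative swing profiles.

        Near the stance boundary the swing ankle blends from a linear
        (Taylor) continuation of the *absolute* stance path into these
        nominal polar profiles with a fixed quintic weight; the remaining
        short-wavelength transition content is removed by the smoothing
        pass of the base solve.
        """
        for side in ("r", "l"):
            fp = self.foot_plans[f"foot_{side}"]
            l1, l2, _ = self.geom[side]
            L = l1 + l2
            if side == "r":
                t_b, T = fp.window[1], horizon
                tk = [t_b, 0.5 * (t_b + T), T]
                r_nom = make_interp_spline(tk, [0.74 * L, 0.60 * L, 0.66 * L], k=2)
                g_nom = make_interp_spline(tk, [-0.75, -0.32, -0.05], k=2)
                sense = "start"
            else:
                t_b = fp.window[0]
                tk = [0.0, 0.5 * t_b, t_b]
                r_nom = make_interp_spline(tk, [0.72 * L, 0.58 * L, 0.72 * L], k=2)
                g_nom = make_interp_spline(tk, [-0.80, -0.10, 0.08], k=2)
                sense = "end"
            eps = 1e-4 if side == "r" else -1e-4
            ank_b = fp.ankle(t_b)
            ank_rate = (ank_b - fp.ankle(t_b - eps)) / eps
            self.swing[f"foot_{side}"] = (r_nom, g_nom, sense, t_b, ank_b, ank_rate)

    def _swing_ankle(self, foot, t, hip):
        """Swing ankle position: blended stance continuation + nominal."""
        r_nom, g_nom, sense, t_b, ank_b, ank_rate = self.swing[foot]
        u = (t - t_b) / self._FADE if sense == "start" else (t_b - t) / self._FADE
        r = float(r_nom(t))
        g = float(g_nom(t))
        nominal = hip + r * np.array([np.sin(g), -np.cos(g)])
        if u >= 1.0:
            return nominal
        w = 1.0 - (10 * u**3 - 15 * u**4 + 6 * u**5)  # 1 at boundary, C2 to 0
        return w * (ank_b + ank_rate * (t - t_b)) + (1.0 - w) * nominal

    def q_internal(self, t, base, trunk_offset=0.0):
        model = self.model
        out = np.empty(model.nq - 3)
        idx = {d: i for i, d in enumerate(model.internal_dofs)}
        out[idx["lumbar"]] = self.trunk(t) + trunk_offset - base[2]
        for side in ("r", "l"):
            l1, l2, _ = self.geom[side]
            fp = self.foot_plans[f"foot_{side}"]
            hip = self._hip(side, t, base)
            if fp.in_stance(t):
                ankle = fp.ankle(t)
            else:
                ankle = self._swing_ankle(f"foot_{side}", t, hip)
            theta_t, qk, clamped = _leg_ik(l1, l2, hip, ankle)
            self.n_clamped += clamped
            out[idx[f"hip_{side}"]] = theta_t - base[2]
            out[idx[f"knee_{side}"]] = qk
            out[idx[f"ankle_{side}"]] = fp.pitch(t) - (theta_t + qk)
        return out


# ----------------------------------------------------------------------
# pelvis pitch from the unactuated base-rotation row


def _external_generalized(model: ModelSpec, kin):
    """Contact + drag generalized forces for the current kinematics."""
    ext = np.zeros(model.nq)
    masses = np.array([s.mass for s in model.segments])
    for sph in model.contact_spheres:
        i = model.segment_index(sph.segment)
        r = _rot(kin.phi[i]) @ np.asarray(sph.location)
        p = kin.origin[i] + r
        pv = kin.origin_vel[i] + kin.omega[i] * _perp(r)
        f = hunt_crossley_force(sph, p, pv)
        ext[0] += f[0]
        ext[1] += f[1]
        for jd in model._rot_ancestors[i]:
            arm = p - kin.joint_pivot[jd]
            ext[jd] += arm[0] * f[1] - arm[1] * f[0]
    com_v = (masses[:, None] * kin.com_vel).sum(axis=0) / model.total_mass
    com_p = (masses[:, None] * kin.com).sum(axis=0) / model.total_mass
    fd = aerodynamic_drag(com_v[0], model.drag)
    ext[0] += fd
    ext[2] += -(com_p[1] - kin.joint_pivot[2][1]) * fd
    return ext


class _BaseBVP:
    """Zero all three unactuated base EoM rows along the horizon.

    Unknowns per grid node: the trunk-angle correction psi (the rotation
    row's absorber) and pelvis translation corrections (dx, dy) on top of
    the CoM-derived initial guess. Time derivatives are central finite
    differences on the grid with ghost nodes; boundary conditions pin psi
    to zero at both ends (the rotational forward problem is an unstable
    inverted pendulum, the BVP is well posed) and pin the first two nodes
    of dx and dy (initial position and velocity are part of the study
    conditions). The block-tridiagonal Newton system is assembled with a
    9-colored perturbation scheme; swing-leg paths are re-anchored to the
    current iterate so stance/swing continuity is preserved.
    """

    def __init__(self, model, skel, base0, th_arr, dense, horizon, com_ic):
        self.model = model
        self.skel = skel
        self.dense = dense
        self.horizon = horizon
        self.dt = dense[1] - dense[0]
        self.com_ic = com_ic  # (x0, y0, vx0, vy0) of the whole-body CoM
        n = len(dense)
        # ghost-extended prescribed base (linear extrapolation at the ends)
        self.bx0 = self._extend(base0[:, 0])
        self.by0 = self._extend(base0[:, 1])
        self.th0 = self._extend(th_arr)

    def _extend(self, arr):
        out = np.empty(len(arr) + 2)
        out[1:-1] = arr
        out[0] = 2 * arr[0] - arr[1]
        out[-1] = 2 * arr[-1] - arr[-2]
        return out


    def _residual(self, z):
        n = len(self.dense)
        dt = self.dt
        psi, dx, dy = z.reshape(3, n + 2)
        Q = np.empty((n + 2, self.model.nq))
        for e in range(n + 2):
            t = self.dense[0] + (e - 1) * dt
            base = (self.bx0[e] + dx[e], self.by0[e] + dy[e], self.th0[e])
            Q[e] = np.concatenate(
                [np.array(base), self.skel.q_internal(t, base, psi[e])]
            )
        R = np.empty(3 * n)
        for i in range(n):
            q0 = Q[i + 1]
            v = (Q[i + 2] - Q[i]) / (2 * dt)
            a = (Q[i + 2] - 2 * Q[i + 1] + Q[i]) / (dt * dt)
            kin = forward_kinematics(self.model, q0, v)
            ext = _external_generalized(self.model, kin)
            R[3 * i : 3 * i + 3] = (inverse_dynamics(self.model, q0, v, a) - ext)[:3]
        return R, Q

    def _bc_com(self, Q):
        """Initial-condition residuals: CoM position and velocity at t=0."""
        z = np.zeros(self.model.nq)
        c0, _ = com_state(self.model, GeneralizedState(Q[1], z))
        c1, _ = com_state(self.model, GeneralizedState(Q[2], z))
        x0, y0, vx0, vy0 = self.com_ic
        return np.array([
            c0[0] - x0,
            c0[1] - y0,
            (c1[0] - c0[0]) / self.dt - vx0,
            (c1[1] - c0[1]) / self.dt - vy0,
        ])

    def solve(self, z0=None, tol=1.0, maxiter=10):
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        n = len(self.dense)
        m = 3 * (n + 2)
        z = np.zeros(m) if z0 is None else z0.copy()
        step = 1e-6
        Q = None
        self.skel.build_swing(self.horizon)
        for it in range(maxiter):
            R, Q = self._residual(z)
            bc = self._bc_com(Q)
            worst = np.abs(R).max()
            logger.debug("base BVP iteration %d: max residual %.3f (CoM IC %.4f)",
                         it, worst, np.abs(bc).max())
            if worst < tol and np.abs(bc).max() < 1e-4:
                break
            stride = 3
            rows, cols, vals = [], [], []
            for var in range(3):
                for color in range(stride):
                    zp = z.copy()
                    sl = slice(var * (n + 2) + color, (var + 1) * (n + 2), stride)
                    zp[sl] += step
                    Rp, Qp = self._residual(zp)
                    for i in range(n):
                        for e in range(i, i + 3):  # ghost-extended nodes
                            if e % stride == color:
                                col = var * (n + 2) + e
                                for k in range(3):
                                    rows.append(3 * i + k)
                                    cols.append(col)
                                    vals.append((Rp[3 * i + k] - R[3 * i + k]) / step)
                    # CoM initial-condition rows depend on ext nodes 1, 2
                    bcp = self._bc_com(Qp)
                    for e in (1, 2):
                        if e % stride == color:
                            col = var * (n + 2) + e
                            for k in range(4):
                                d = (bcp[k] - bc[k]) / step
                                if d != 0.0:
                                    rows.append(3 * n + 2 + k)
                                    cols.append(col)
                                    vals.append(d)
            # boundary rows: psi pinned to zero at both true end nodes,
            # then the four CoM initial conditions
            for k, c in enumerate([1, n]):
                rows.append(3 * n + k)
                cols.append(c)
                vals.append(1.0)
            J = sp.csc_matrix((vals, (rows, cols)), shape=(3 * n + 6, m))
            rhs = np.concatenate([-R, [-z[1], -z[n]], -bc])
            delta = spla.spsolve(J, rhs)
            # step safeguard against wild Newton excursions
            scale = min(1.0, 0.5 / max(np.abs(delta).max(), 1e-9)) \
                if np.abs(delta).max() > 0.5 else 1.0
            z = z + scale * delta
        return z, worst, Q


# ----------------------------------------------------------------------
# public operations


def generate_reference_kinematics(cfg: SynthConfig, model: ModelSpec | None = None):
    """Generate the scripted, dynamically consistent coordinate series.

    Returns ``(times, q, v, a, model, diagnostics)`` at the configured
    sampling rate; see the module docstring for the construction.
    """
    model = model or default_model(cfg.body_mass, cfg.stature)
    rng = np.random.default_rng(cfg.seed)
    T = cfg.horizon
    dense = np.linspace(0.0, T, max(int(T * 2000) + 1, 500))
    plan = _ComPlan(cfg, model, dense)
    foot_plans = {
        f: _FootPlan(model, cfg, plan, f, rng) for f in ("foot_r", "foot_l")
    }
    jit = 1.0 + cfg.plan_jitter * rng.uniform(-1, 1)
    trunk = make_interp_spline(
        [0.0, 0.5 * T, T], [-0.38, -0.33 * jit, -0.28], k=2
    )
    skel = _Skeleton(model, foot_plans, trunk)

    # solve the coupled base BVP (trunk correction + pelvis translation
    # corrections) so all three unactuated base rows vanish; the outer
    # loop re-anchors the touchdown leads against the realized CoM
    base0 = np.column_stack([plan.cx - 0.05, plan.cy - 0.07])
    th_arr = np.full_like(dense, -0.10)
    n = len(dense)
    z = None
    bvp_residual = np.inf
    Q = None
    for outer in range(cfg.sweeps):
        com_ic = (plan.cx[0], plan.cy[0], plan.vx[0], plan.vy[0])
        bvp = _BaseBVP(model, skel, base0, th_arr, dense, T, com_ic)
        z, bvp_residual, Q = bvp.solve(z0=z)
        q_nodes = Q[1:-1]
        # realized CoM at the touchdown instants; re-anchor the leads
        i_td_l = int(np.searchsorted(dense, cfg.stance_l[0]))
        lead_errs = {}
        for foot, i_td in (("foot_r", 0), ("foot_l", i_td_l)):
            st = GeneralizedState(q_nodes[i_td], np.zeros(model.nq))
            com_td, _ = com_state(model, st)
            fp = foot_plans[foot]
            want = com_td[0] + cfg.touchdown_lead
            lead_errs[foot] = float(fp.toe_x(dense[i_td]) + fp.x_offset - want)
            fp.x_offset -= lead_errs[foot]
        logger.info("outer %d: BVP residual %.3f, lead errors %s, clamped IK %d",
                    outer, bvp_residual, {k: round(v, 4) for k, v in lead_errs.items()},
                    skel.n_clamped)
        skel.n_clamped = 0
        if max(abs(v) for v in lead_errs.values()) < 2e-3 and bvp_residual < 1.0:
            break

    psi_arr = z.reshape(3, n + 2)[0][1:-1]
    q_all = Q[1:-1]
    # velocities/accelerations by the same ghost-extended central
    # differences the BVP zeroed, so the residual carries over exactly
    dt = dense[1] - dense[0]
    v_all = (Q[2:] - Q[:-2]) / (2 * dt)
    a_all = (Q[2:] - 2 * Q[1:-1] + Q[:-2]) / (dt * dt)

    times = np.arange(0.0, T + 0.5 / cfg.sampling_rate, 1.0 / cfg.sampling_rate)
    times = times[times <= T + 1e-12]
    idx = np.clip(np.round(times / dt).astype(int), 0, n - 1)
    times = dense[idx]
    q = q_all[idx]
    v = v_all[idx]
    a = a_all[idx]
    diagnostics = {
        "base_bvp_residual": float(bvp_residual),
        "trunk_correction_range": [float(psi_arr.min()), float(psi_arr.max())],
        "clamped_ik": int(skel.n_clamped),
        "lead_errors": {k: float(v) for k, v in lead_errs.items()},
    }
    return times, q, v, a, model, diagnostics


def derive_consistent_kinetics(times, q, v, a, model: ModelSpec, cfg: SynthConfig,
                               diagnostics: dict | None = None) -> ExperimentData:
    """GRF from the contact model and net moments from the equation of motion.

    The internal-DOF rows are satisfied exactly by construction (the
    moments are read off the residual); the three base rows are a
    diagnostic of the construction fidelity and must stay below the
    configured threshold.
    """
    diagnostics = dict(diagnostics or {})
    n = len(times)
    n_int = model.nq - 3
    grf_cols = {f"{f}_{c}": np.zeros(n) for f in model.feet for c in ("x", "y")}
    moments = np.zeros((n, n_int))
    base_residual = np.zeros((n, 3))
    for i in range(n):
        st = GeneralizedState(q[i], v[i], times[i])
        per_sphere, per_foot, _ = contact_grf(model, st)
        for f in model.feet:
            grf_cols[f"{f}_x"][i] = per_foot[f][0]
            grf_cols[f"{f}_y"][i] = per_foot[f][1]
        _, com_v = com_state(model, st)
        drag = np.array([aerodynamic_drag(com_v[0], model.drag), 0.0])
        r = eom_residual(model, st, a[i], np.zeros(n_int), per_sphere.reshape(-1), drag)
        moments[i] = r[3:]
        base_residual[i] = r[:3]

    worst = np.abs(base_residual).max(axis=0)
    diagnostics["base_residual_max"] = worst.tolist()
    if np.any(worst > cfg.base_residual_threshold):
        raise RuntimeError(
            f"base-row residual {worst} exceeds threshold "
            f"{cfg.base_residual_threshold}; diagnostics: {diagnostics}"
        )

    grf = pd.DataFrame(grf_cols)
    stance_windows = {}
    for f in model.feet:
        wins = detect_stance(grf[f"{f}_y"].to_numpy(), times)
        if wins:
            stance_windows[f] = max(wins, key=lambda w: w[1] - w[0])
    st0 = GeneralizedState(q[0], v[0])
    stf = GeneralizedState(q[-1], v[-1])
    _, v0 = com_state(model, st0)
    _, vf = com_state(model, stf)
    diagnostics.update({"com_vx0": float(v0[0]), "com_vxf": float(vf[0]), "seed": cfg.seed})
    coords = pd.DataFrame(q, columns=model.dof_names)
    mom = pd.DataFrame(moments, columns=model.internal_dofs)
    exp = ExperimentData(
        time=times,
        coords=coords,
        grf=grf,
        moments=mom,
        body_mass=cfg.body_mass,
        stance_windows=stance_windows,
        trial_id=f"synth-seed{cfg.seed}",
        metadata={
            "diagnostics": diagnostics,
            "velocities": {d: v[:, i].tolist() for i, d in enumerate(model.dof_names)},
            "accelerations": {d: a[:, i].tolist() for i, d in enumerate(model.dof_names)},
        },
    )
    return exp


def add_noise_and_package(exp: ExperimentData, cfg: SynthConfig) -> ExperimentData:
    """Seeded Gaussian measurement noise on coordinates (and optionally GRF)."""
    rng = np.random.default_rng(cfg.seed + 10_000)
    coords = exp.coords.copy()
    if cfg.noise_std_q > 0:
        for c in coords.columns:
            std = cfg.noise_std_trans if c in ("base_x", "base_y") else cfg.noise_std_q
            coords[c] = coords[c] + rng.normal(0.0, std, len(coords))
    grf = exp.grf.copy()
    if cfg.noise_std_grf > 0:
        for c in grf.columns:
            grf[c] = grf[c] + rng.normal(0.0, cfg.noise_std_grf, len(grf))
    meta = dict(exp.metadata)
    meta["noise"] = {"std_q": cfg.noise_std_q, "std_trans": cfg.noise_std_trans,
                     "std_grf": cfg.noise_std_grf, "seed": cfg.seed}
    return ExperimentData(
        time=exp.time, coords=coords, grf=grf, moments=exp.moments.copy(),
        body_mass=exp.body_mass, stance_windows=dict(exp.stance_windows),
        trial_id=exp.trial_id + "-noisy", metadata=meta,
    )


def generate_experiment(cfg: SynthConfig, model: ModelSpec | None = None) -> ExperimentData:
    """Full pipeline: scripted kinematics -> consistent kinetics -> noise."""
    times, q, v, a, model, diag = generate_reference_kinematics(cfg, model)
    exp = derive_consistent_kinetics(times, q, v, a, model, cfg, diag)
    if cfg.noise_std_q > 0 or cfg.noise_std_grf > 0:
        exp = add_noise_and_package(exp, cfg)
    return exp
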