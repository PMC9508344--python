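"""Hill-type muscle-tendon units in the implicit tendon-force-state form.

Each muscle-tendon unit (MTU) is a three-element Hill model: contractile
element with active force-length and force-velocity characteristics,
parallel passive fiber elasticity, and a series elastic tendon. The state
variables are the normalized tendon force (force / maximal isometric force)
and the activation; contraction dynamics are imposed as an algebraic
equilibrium residual in the tendon force, and activation dynamics as the
pair of rate inequality constraints equivalent to the first-order
activation ODE with separate activation/deactivation time constants.

Musculotendon geometry (length, lengthening velocity, moment arms) is
described by separable polynomials of the spanned coordinates, one
polynomial per degree of freedom, which keeps lengths and moment arms
smooth and consistent (moment arm = -dL/dq).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P

from . import hill_constants as HC

logger = logging.getLogger(__name__)

__all__ = [
    "HillCurves",
    "MTUParams",
    "MuscleState",
    "ActivationParams",
    "mtu_geometry",
    "hill_equilibrium_residual",
    "tendon_force_to_length",
    "activation_rate_constraints",
    "activation_ode_rate",
    "muscle_moments",
    "default_leg_muscles",
]


class HillCurves:
    """Characteristic curves, normalized so that the active force-length
    curve equals 1 at optimal fiber length and the force-velocity curve
    equals 1 at zero velocity."""

    def __init__(self, tendon=None, active_fl=None, force_velocity=None, passive_fl=None):
        self.tendon = dict(tendon or HC.TENDON)
        self.active_fl = [tuple(r) for r in (active_fl or HC.ACTIVE_FL)]
        self.force_velocity = dict(force_velocity or HC.FORCE_VELOCITY)
        self.passive_fl = dict(passive_fl or HC.PASSIVE_FL)
        self._act_norm = 1.0
        self._act_norm = self.active_force_length(1.0)
        self._fv_norm = 1.0
        self._fv_norm = self.force_velocity_curve(0.0)

    # tendon force-length: normalized force as function of l_T / l_slack
    def tendon_force(self, lt_norm):
        c = self.tendon
        return c["c1"] * np.exp(c["kT"] * (lt_norm - c["c2"])) - c["c3"]

    def tendon_inverse(self, ft_norm):
        """Normalized tendon length at normalized tendon force ``ft_norm``."""
        c = self.tendon
        return c["c2"] + np.log((ft_norm + c["c3"]) / c["c1"]) / c["kT"]

    def tendon_inverse_slope(self, ft_norm):
        c = self.tendon
        return 1.0 / (c["kT"] * (ft_norm + c["c3"]))

    @property
    def tendon_slack_force(self):
        """Normalized force at which the tendon is exactly slack (length 1)."""
        c = self.tendon
        return c["c1"] * np.exp(-c["kT"] * (c["c2"] - 1.0)) - c["c3"]

    def active_force_length(self, l_norm):
        out = 0.0
        for b1, b2, b3, b4 in self.active_fl:
            out = out + b1 * np.exp(-0.5 * (l_norm - b2) ** 2 / (b3 + b4 * l_norm) ** 2)
        return out / self._act_norm

    def force_velocity_curve(self, v_norm):
        d = self.force_velocity
        z = d["d2"] * v_norm + d["d3"]
        return (d["d1"] * np.log(z + np.sqrt(z * z + 1.0)) + d["d4"]) / self._fv_norm

    def passive_force_length(self, l_norm):
        p = self.passive_fl
        return (np.exp(p["kpe"] * (l_norm - 1.0) / p["e0"]) - 1.0) / (np.exp(p["kpe"]) - 1.0)


@dataclass
class MTUParams:
    name: str
    dofs: list[str]
    fmax: float  # N
    l_opt: float  # optimal fiber length, m
    l_slack: float  # tendon slack length, m
    pennation_opt: float = 0.0  # rad, at optimal fiber length
    vmax: float = 10.0  # maximal contraction velocity, optimal lengths / s
    base_length: float = 0.0  # constant term of the geometry polynomial, m
    poly_coeffs: dict[str, list[float]] = field(default_factory=dict)
    q_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.fmax <= 0 or self.l_opt <= 0 or self.l_slack <= 0:
            raise ValueError(f"{self.name}: Fmax and lengths must be > 0")
        if not (0.0 <= self.pennation_opt < np.pi / 2):
            raise ValueError(f"{self.name}: pennation must lie in [0, pi/2)")


@dataclass
class MuscleState:
    ft_norm: float  # normalized tendon force
    activation: float

    def __post_init__(self):
        if not (0.0 <= np.real(self.activation) <= 1.0):
            raise ValueError("activation must lie in [0, 1]")


@dataclass
class ActivationParams:
    tau_act: float = 0.015  # s
    tau_deact: float = 0.060  # s

    def __post_init__(self):
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_act >= self.tau_deact:
            raise ValueError("activation must be faster than deactivation")


def mtu_geometry(q: dict[str, float], params: MTUParams, v: dict[str, float] | None = None):
    """MTU length, lengthening velocity and moment arms at coordinates ``q``.

    ``q`` (and optionally ``v``) map DOF names to values. Returns
    ``(length, velocity, {dof: moment_arm})`` with moment arm defined as
    ``-dL/dq``; velocity is zero if ``v`` is omitted.
    """
    length = params.base_length
    vel = 0.0
    arms = {}
    for dof in params.dofs:
        coeffs = np.asarray(params.poly_coeffs.get(dof, [0.0]), dtype=float)
        qj = q[dof]
        rng = params.q_range.get(dof)
        if rng is not None:
            qr = np.real(np.asarray(qj))
            if np.any(qr < rng[0]) or np.any(qr > rng[1]):
                logger.warning(
                    "%s: coordinate %s outside polynomial validity range %s; extrapolating",
                    params.name, dof, rng,
                )
        length = length + P.polyval(qj, coeffs)
        dl = P.polyval(qj, P.polyder(coeffs))
        arms[dof] = -dl
        if v is not None:
            vel = vel + dl * v[dof]
    return length, vel, arms


def tendon_force_to_length(ft_norm, params: MTUParams, curves: HillCurves):
    """Tendon length in metres at normalized tendon force ``ft_norm``."""
    return params.l_slack * curves.tendon_inverse(ft_norm)


def hill_residual_raw(q, v, ft_norm, activation, params, curves, dft_dt=0.0):
    """Hill equilibrium residual on raw state values (no validation).

    Used inside optimal-control constraint callbacks, where states may be
    complex-perturbed for derivative evaluation.
    """
    l_mt, v_mt, _ = mtu_geometry(q, params, v)
    l_t = params.l_slack * curves.tendon_inverse(ft_norm)
    proj = l_mt - l_t
    w = params.l_opt * np.sin(params.pennation_opt)
    l_m = np.sqrt(proj * proj + w * w) if params.pennation_opt > 0 else proj
    cos_theta = proj / l_m if params.pennation_opt > 0 else 1.0
    v_t = params.l_slack * curves.tendon_inverse_slope(ft_norm) * dft_dt
    v_m = (v_mt - v_t) * cos_theta
    v_norm = v_m / (params.vmax * params.l_opt)
    l_norm = l_m / params.l_opt
    f_ce = activation * curves.active_force_length(l_norm) * curves.force_velocity_curve(v_norm)
    f_pe = curves.passive_force_length(l_norm)
    return ft_norm - cos_theta * (f_ce + f_pe)


def hill_equilibrium_residual(
    q: dict[str, float],
    v: dict[str, float],
    muscle: MuscleState,
    params: MTUParams,
    curves: HillCurves,
    dft_dt: float = 0.0,
):
    """Implicit Hill equilibrium residual (dimensionless force).

    ``F_T - cos(theta) * (a * f_act(lM) * f_v(vM) + f_pass(lM))`` with the
    fiber state recovered from the tendon force through the tendon curve and
    the constant-thickness pennation model, and the fiber velocity from the
    MTU lengthening velocity and the tendon force rate ``dft_dt`` (1/s).
    """
    l_mt, v_mt, _ = mtu_geometry(q, params, v)
    l_t = tendon_force_to_length(muscle.ft_norm, params, curves)
    proj = l_mt - l_t  # fiber length projected on the tendon line
    w = params.l_opt * np.sin(params.pennation_opt)
    l_m = np.sqrt(proj * proj + w * w) if params.pennation_opt > 0 else proj
    if np.real(l_m) <= 0:
        raise ValueError(f"{params.name}: non-positive fiber length")
    cos_theta = proj / l_m if params.pennation_opt > 0 else 1.0
    v_t = params.l_slack * curves.tendon_inverse_slope(muscle.ft_norm) * dft_dt
    v_m = (v_mt - v_t) * cos_theta
    v_norm = v_m / (params.vmax * params.l_opt)
    l_norm = l_m / params.l_opt
    f_ce = muscle.activation * curves.active_force_length(l_norm) * curves.force_velocity_curve(v_norm)
    f_pe = curves.passive_force_length(l_norm)
    return muscle.ft_norm - cos_theta * (f_ce + f_pe)


def activation_rate_constraints(a, u_adot, params: ActivationParams):
    """Activation-dynamics inequality pair ``(g_lower, g_upper)``.

    Feasible iff ``g_lower = u_adot + a / tau_deact >= 0`` (cannot deactivate
    faster than the deactivation time constant allows) and
    ``g_upper = u_adot + a / tau_act - 1 / tau_act <= 0`` (cannot activate
    faster than full excitation drives).
    """
    g_lower = u_adot + a / params.tau_deact
    g_upper = u_adot + a / params.tau_act - 1.0 / params.tau_act
    return g_lower, g_upper


def activation_ode_rate(a, excitation, params: ActivationParams):
    """First-order activation ODE rate for excitation ``e``: rise toward
    ``e`` with the activation time constant, decay with the deactivation
    time constant. The rate-inequality constraints are exactly the envelope
    of these rates over e in [0, 1]."""
    if excitation > a:
        return (excitation - a) / params.tau_act
    return (excitation - a) / params.tau_deact


def muscle_moments(
    q: dict[str, float],
    muscles: list[MuscleState],
    params_list: list[MTUParams],
    dof_names: list[str],
):
    """Net moment contribution of all MTUs on each DOF in ``dof_names``."""
    if len(muscles) != len(params_list):
        raise ValueError("muscle state and parameter lists differ in length")
    first = muscles[0].ft_norm if muscles else 0.0
    out = {d: 0.0 * first for d in dof_names}
    for st, p in zip(muscles, params_list):
        _, _, arms = mtu_geometry(q, p)
        for dof, r in arms.items():
            if dof in out:
                out[dof] = out[dof] + st.ft_norm * p.fmax * r
    return np.array([out[d] for d in dof_names])


def _mtu(name, fmax, l_opt, l_slack, penn, arms, quad=None, q0=None):
    """Helper: MTU with constant (or mildly quadratic) moment arms.

    ``arms`` maps DOF -> moment arm at q=0 (m); the geometry polynomial is
    L = base - sum(arm * q) (+ 0.5*quad*q^2 terms). ``base_length`` is set
    so that the fiber sits at optimal length in the reference pose ``q0``.
    """
    coeffs = {}
    for d, r in arms.items():
        c = [0.0, -r]
        if quad and d in quad:
            c.append(0.5 * quad[d])
        coeffs[d] = c
    p = MTUParams(
        name=name, dofs=list(arms), fmax=fmax, l_opt=l_opt, l_slack=l_slack,
        pennation_opt=penn, poly_coeffs=coeffs,
        q_range={d: (-2.6, 2.6) for d in arms},
    )
    q0 = q0 or {d: 0.0 for d in arms}
    delta = sum(P.polyval(q0[d], np.asarray(coeffs[d])) for d in arms)
    p.base_length = l_slack * 1.0 + l_opt * np.cos(penn) - delta
    return p


def default_leg_muscles(side: str) -> list[MTUParams]:
    """Eight sagittal-plane MTUs for one leg of the planar model.

    Moment arms and force parameters are representative adult values; the
    geometry polynomials are linear (constant moment arms) except the
    biarticular units, which get a small quadratic term at the knee.
    """
    s = side
    hip, knee, ankle = f"hip_{s}", f"knee_{s}", f"ankle_{s}"
    return [
        _mtu(f"iliopsoas_{s}", 1500.0, 0.10, 0.13, 0.14, {hip: 0.043}),
        _mtu(f"glutei_{s}", 2200.0, 0.16, 0.12, 0.09, {hip: -0.062}),
        _mtu(f"hamstrings_{s}", 2600.0, 0.11, 0.33, 0.21, {hip: -0.060, knee: -0.034}, quad={knee: 0.01}),
        _mtu(f"rectfem_{s}", 1200.0, 0.11, 0.34, 0.24, {hip: 0.040, knee: 0.045}, quad={knee: -0.012}),
        _mtu(f"vasti_{s}", 5000.0, 0.09, 0.22, 0.08, {knee: 0.044}),
        _mtu(f"gastroc_{s}", 2500.0, 0.06, 0.39, 0.21, {knee: -0.018, ankle: -0.048}),
        _mtu(f"soleus_{s}", 3600.0, 0.05, 0.25, 0.47, {ankle: -0.048}),
        _mtu(f"tibant_{s}", 1100.0, 0.07, 0.22, 0.17, {ankle: 0.037}),
    ]
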