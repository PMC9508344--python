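"""Planar multibody skeleton with floating base and environment forces.

The skeleton is a kinematic tree of rigid segments in the sagittal plane:
the base segment (pelvis) carries three floating degrees of freedom
(anterior-posterior translation x, vertical translation y, rotation), and
every other segment attaches to its parent through a revolute joint.
Conventions: +x is the direction of travel, +y is up, angles are
counter-clockwise positive in radians. With all joint angles zero the legs
hang vertically, the trunk points up and the feet are flat; hip flexion is
positive, knee flexion negative, ankle dorsiflexion positive, and forward
trunk inclination negative, matching standard sagittal gait reporting.

Environment forces: smooth Hunt-Crossley contact spheres on the feet,
linear rotational springs at optional metatarsophalangeal (MTP) joints,
and an aerodynamic drag force applied at the whole-body centre of mass.
All force laws are C1-smooth and complex-step differentiable so they can
sit inside gradient-based optimal control constraints.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._smooth import smooth_pos, softplus

__all__ = [
    "Segment",
    "Joint",
    "ContactSphereParams",
    "DragParams",
    "ModelSpec",
    "GeneralizedState",
    "KinematicsCache",
    "forward_kinematics",
    "inverse_dynamics",
    "mass_matrix",
    "bias_forces",
    "gravity_forces",
    "eom_residual",
    "contact_grf",
    "sphere_forces",
    "hunt_crossley_force",
    "mtp_spring_moment",
    "mtp_spring_torques",
    "aerodynamic_drag",
    "com_state",
    "default_model",
    "model_to_dict",
    "model_from_dict",
]

_BASE_DOFS = 3


@dataclass
class Segment:
    name: str
    mass: float  # kg
    inertia: float  # kg m^2 about the CoM, out-of-plane axis
    length: float  # m, nominal long-axis length (bookkeeping only)
    com_offset: tuple[float, float]  # m, proximal joint -> CoM, segment frame


@dataclass
class Joint:
    """Revolute joint attaching ``child`` to ``parent``.

    ``location`` is the joint anchor expressed in the parent segment frame.
    The joint angle is the child's orientation relative to the parent.
    """

    name: str
    parent: str
    child: str
    location: tuple[float, float]


@dataclass
class ContactSphereParams:
    segment: str
    location: tuple[float, float]  # sphere centre in the segment frame, m
    radius: float  # m
    stiffness: float = 3.0e6  # N / m^1.5
    dissipation: float = 2.0  # s / m
    friction: float = 0.8
    velocity_smoothing: float = 0.05  # m/s, tanh friction scale
    penetration_smoothing: float = 1.0e-4  # m, softplus positive-part scale

    def __post_init__(self):
        if self.radius <= 0 or self.stiffness <= 0:
            raise ValueError("contact sphere radius and stiffness must be > 0")
        if self.dissipation < 0:
            raise ValueError("contact dissipation must be >= 0")
        if self.velocity_smoothing <= 0 or self.penetration_smoothing <= 0:
            raise ValueError("smoothing scales must be > 0")


@dataclass
class DragParams:
    air_density: float = 1.2  # kg/m^3
    drag_coefficient: float = 0.9
    frontal_area: float = 0.5  # m^2

    def __post_init__(self):
        if min(self.air_density, self.drag_coefficient, self.frontal_area) <= 0:
            raise ValueError("drag parameters must be > 0")


@dataclass
class GeneralizedState:
    q: np.ndarray
    v: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q)
        self.v = np.asarray(self.v)
        if self.q.shape != self.v.shape:
            raise ValueError("q and v must have the same length")
        if not (np.all(np.isfinite(np.real(self.q))) and np.all(np.isfinite(np.real(self.v)))):
            raise ValueError("state contains non-finite entries")


class ModelSpec:
    """Planar model description: segments, joint tree, environment forces.

    The first segment is the floating base. DOF ordering is
    ``[base_x, base_y, base_rot, <joints in tree order>]``; the actuator
    map assigns each internal DOF one of ``{"muscle", "torque", "reserve"}``.
    """

    def __init__(
        self,
        segments: list[Segment],
        joints: list[Joint],
        gravity: float = 9.80665,
        contact_spheres: list[ContactSphereParams] | None = None,
        drag: DragParams | None = None,
        mtp_joints: list[str] | None = None,
        mtp_spring_stiffness: float = 25.0,
        mtp_neutral_angle: float = 0.0,
        actuator_map: dict[str, str] | None = None,
    ):
        self.segments = segments
        self.joints = joints
        self.gravity = float(gravity)
        self.contact_spheres = contact_spheres or []
        self.drag = drag or DragParams()
        self.mtp_joints = mtp_joints or []
        self.mtp_spring_stiffness = float(mtp_spring_stiffness)
        self.mtp_neutral_angle = float(mtp_neutral_angle)

        names = [s.name for s in segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        self._seg_index = {n: i for i, n in enumerate(names)}
        for s in segments:
            if s.mass <= 0 or s.inertia <= 0:
                raise ValueError(f"segment {s.name}: mass and inertia must be > 0")
        for j in joints:
            if j.parent not in self._seg_index or j.child not in self._seg_index:
                raise ValueError(f"joint {j.name}: unknown parent or child segment")
        for c in self.contact_spheres:
            if c.segment not in self._seg_index:
                raise ValueError(f"contact sphere references unknown segment {c.segment}")
        for m in self.mtp_joints:
            if m not in [j.name for j in joints]:
                raise ValueError(f"MTP joint {m} is not a joint of the model")

        self.dof_names = ["base_x", "base_y", "base_rot"] + [j.name for j in joints]
        self.nq = len(self.dof_names)
        self.internal_dofs = self.dof_names[_BASE_DOFS:]
        # parent joint per segment (base has none); verify tree order
        self._parent_joint: list[Joint | None] = [None] * len(segments)
        seen = {segments[0].name}
        for j in joints:
            if j.parent not in seen:
                raise ValueError("joints must be listed in tree order (parent first)")
            self._parent_joint[self._seg_index[j.child]] = j
            seen.add(j.child)
        if len(seen) != len(segments):
            raise ValueError("some segments are not connected to the tree")

        self.actuator_map = dict(actuator_map or {})
        for d in self.internal_dofs:
            self.actuator_map.setdefault(d, "torque")
        for d, kind in self.actuator_map.items():
            if d not in self.internal_dofs:
                raise ValueError(f"actuator map references unknown DOF {d}")
            if kind not in ("muscle", "torque", "reserve"):
                raise ValueError(f"unknown actuator kind {kind!r} for DOF {d}")

        self.total_mass = float(sum(s.mass for s in segments))
        self.feet = sorted(
            {c.segment for c in self.contact_spheres},
            key=lambda n: ("_l" in n, n),
        )
        # ancestor rotational DOF indices per segment (for Jacobians)
        self._rot_ancestors: list[list[int]] = []
        for i, s in enumerate(segments):
            chain = [2]  # base rotation
            k = i
            while self._parent_joint[k] is not None:
                j = self._parent_joint[k]
                chain.append(_BASE_DOFS + joints.index(j))
                k = self._seg_index[j.parent]
            self._rot_ancestors.append(sorted(chain))

    def dof_index(self, name: str) -> int:
        return self.dof_names.index(name)

    def segment_index(self, name: str) -> int:
        return self._seg_index[name]


def _rot(phi):
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def _perp(v):
    """90-degree counter-clockwise rotation: z_hat x v."""
    return np.array([-v[1], v[0]])


@dataclass
class KinematicsCache:
    """Per-segment pose, velocity and (optionally) acceleration."""

    origin: np.ndarray  # (nseg, 2) proximal joint position
    origin_vel: np.ndarray
    phi: np.ndarray  # (nseg,)
    omega: np.ndarray
    com: np.ndarray  # (nseg, 2)
    com_vel: np.ndarray
    com_acc: np.ndarray | None = None
    alpha: np.ndarray | None = None
    joint_pivot: np.ndarray | None = None  # (nq, 2) pivot of each rotational DOF


def forward_kinematics(model: ModelSpec, q, v, vdot=None) -> KinematicsCache:
    """Propagate pose, velocity and optional acceleration down the tree."""
    q = np.asarray(q)
    v = np.asarray(v)
    n = len(model.segments)
    dt = np.result_type(q, v, float)
    origin = np.zeros((n, 2), dtype=dt)
    ovel = np.zeros((n, 2), dtype=dt)
    oacc = np.zeros((n, 2), dtype=dt) if vdot is not None else None
    phi = np.zeros(n, dtype=dt)
    omega = np.zeros(n, dtype=dt)
    alpha = np.zeros(n, dtype=dt) if vdot is not None else None
    com = np.zeros((n, 2), dtype=dt)
    cvel = np.zeros((n, 2), dtype=dt)
    cacc = np.zeros((n, 2), dtype=dt) if vdot is not None else None
    pivot = np.zeros((model.nq, 2), dtype=dt)

    origin[0] = q[:2]
    ovel[0] = v[:2]
    phi[0] = q[2]
    omega[0] = v[2]
    if vdot is not None:
        vdot = np.asarray(vdot)
        oacc[0] = vdot[:2]
        alpha[0] = vdot[2]
    pivot[2] = origin[0]

    for i, s in enumerate(model.segments):
        if i > 0:
            j = model._parent_joint[i]
            p = model.segment_index(j.parent)
            jd = _BASE_DOFS + model.joints.index(j)
            r = _rot(phi[p]) @ np.asarray(j.location)
            origin[i] = origin[p] + r
            ovel[i] = ovel[p] + omega[p] * _perp(r)
            phi[i] = phi[p] + q[jd]
            omega[i] = omega[p] + v[jd]
            if vdot is not None:
                oacc[i] = oacc[p] + alpha[p] * _perp(r) - omega[p] ** 2 * r
                alpha[i] = alpha[p] + vdot[jd]
            pivot[jd] = origin[i]
        rc = _rot(phi[i]) @ np.asarray(s.com_offset)
        com[i] = origin[i] + rc
        cvel[i] = ovel[i] + omega[i] * _perp(rc)
        if vdot is not None:
            cacc[i] = oacc[i] + alpha[i] * _perp(rc) - omega[i] ** 2 * rc
    return KinematicsCache(origin, ovel, phi, omega, com, cvel, cacc, alpha, pivot)


def _com_jacobians(model: ModelSpec, kin: KinematicsCache):
    """Translational CoM Jacobian (nseg, 2, nq); rotational rows are stored
    in ``model._rot_ancestors`` (entries of 1)."""
    n = len(model.segments)
    J = np.zeros((n, 2, model.nq), dtype=kin.com.dtype)
    for i in range(n):
        J[i, 0, 0] = 1.0
        J[i, 1, 1] = 1.0
        for jd in model._rot_ancestors[i]:
            J[i, :, jd] = _perp(kin.com[i] - kin.joint_pivot[jd])
    return J


def _point_jacobian(model: ModelSpec, kin: KinematicsCache, seg: int, p):
    Jp = np.zeros((2, model.nq), dtype=kin.com.dtype)
    Jp[0, 0] = 1.0
    Jp[1, 1] = 1.0
    for jd in model._rot_ancestors[seg]:
        Jp[:, jd] = _perp(p - kin.joint_pivot[jd])
    return Jp


def inverse_dynamics(model: ModelSpec, q, v, vdot):
    """Generalized forces balancing inertia and gravity: ID(q, v, a).

    Returns the vector ``M(q) a + C(q, v) + G(q)`` (no external forces, no
    joint torques) by the virtual-work assembly over segments.
    """
    kin = forward_kinematics(model, q, v, vdot)
    J = _com_jacobians(model, kin)
    g = np.array([0.0, -model.gravity])
    out = np.zeros(model.nq, dtype=kin.com.dtype)
    for i, s in enumerate(model.segments):
        out += J[i].T @ (s.mass * (kin.com_acc[i] - g))
        for jd in model._rot_ancestors[i]:
            out[jd] += s.inertia * kin.alpha[i]
    return out


def mass_matrix(model: ModelSpec, q) -> np.ndarray:
    z = np.zeros(model.nq)
    G = inverse_dynamics(model, q, z, z)
    M = np.empty((model.nq, model.nq))
    for j in range(model.nq):
        e = np.zeros(model.nq)
        e[j] = 1.0
        M[:, j] = inverse_dynamics(model, q, z, e) - G
    return M


def gravity_forces(model: ModelSpec, q) -> np.ndarray:
    z = np.zeros(model.nq)
    return inverse_dynamics(model, q, z, z)


def bias_forces(model: ModelSpec, q, v) -> np.ndarray:
    """Centrifugal/Coriolis vector C(q, v)."""
    z = np.zeros(model.nq)
    return inverse_dynamics(model, q, v, z) - inverse_dynamics(model, q, z, z)


def eom_residual(model: ModelSpec, state: GeneralizedState, u_vdot, tau, grf, drag):
    """Implicit equation-of-motion residual, one entry per DOF.

    ``tau`` holds the net internal-DOF moments (muscles + actuators +
    reserves + springs), ``grf`` the per-sphere planar contact forces
    (flattened, 2 entries per sphere) applied at the sphere centres, and
    ``drag`` a planar force applied at the whole-body CoM. The residual is
    ``M(q) u_vdot + C(q, v) + G(q) - J_ext^T ext - [0; tau]`` and vanishes
    exactly when the supplied accelerations are dynamically consistent.
    Linear in ``u_vdot``, ``tau``, ``grf`` and ``drag``.
    """
    q, v = state.q, state.v
    u_vdot = np.asarray(u_vdot)
    tau = np.asarray(tau)
    grf = np.asarray(grf)
    drag = np.asarray(drag)
    n_int = model.nq - _BASE_DOFS
    if len(q) != model.nq or len(u_vdot) != model.nq:
        raise ValueError("state/acceleration dimension mismatch")
    if len(tau) != n_int:
        raise ValueError("tau must have one entry per internal DOF")
    if len(grf) != 2 * len(model.contact_spheres):
        raise ValueError("grf must have 2 entries per contact sphere")
    for arr in (q, v, u_vdot, tau, grf, drag):
        if not np.all(np.isfinite(np.real(arr))):
            raise ValueError("non-finite inputs")

    res = inverse_dynamics(model, q, v, u_vdot)
    kin = forward_kinematics(model, q, v)
    # contact forces at sphere centres
    for k, sph in enumerate(model.contact_spheres):
        i = model.segment_index(sph.segment)
        p = kin.origin[i] + _rot(kin.phi[i]) @ np.asarray(sph.location)
        Jp = _point_jacobian(model, kin, i, p)
        res -= Jp.T @ grf[2 * k : 2 * k + 2]
    # drag at whole-body CoM
    Jc = _com_jacobians(model, kin)
    Jcom = np.tensordot(
        np.array([s.mass for s in model.segments]) / model.total_mass, Jc, axes=(0, 0)
    )
    res -= Jcom.T @ drag
    res[_BASE_DOFS:] -= tau
    return res


def hunt_crossley_force(sph: ContactSphereParams, center, center_vel):
    """Planar smooth Hunt-Crossley force on one sphere vs the ground y = 0.

    Normal: ``k * pen^(3/2) * (1 + d * pen_rate)`` with the penetration
    passed through a softplus positive part and the dissipation bracket
    smoothly clamped at zero. Tangential: regularized Coulomb friction
    ``-mu * Fn * tanh(v_slip / v_scale)``.
    """
    pen = sph.radius - center[1]
    pen_rate = -center_vel[1]
    pen_s = softplus(pen, sph.penetration_smoothing)
    bracket = smooth_pos(1.0 + sph.dissipation * pen_rate, 0.05)
    fn = sph.stiffness * pen_s ** 1.5 * bracket
    ft = -sph.friction * fn * np.tanh(center_vel[0] / sph.velocity_smoothing)
    return np.array([ft, fn])


def sphere_forces(model: ModelSpec, state: GeneralizedState) -> np.ndarray:
    """Per-sphere planar Hunt-Crossley contact forces, shape (nsphere, 2)."""
    kin = forward_kinematics(model, state.q, state.v)
    out = np.zeros((len(model.contact_spheres), 2), dtype=kin.com.dtype)
    for k, sph in enumerate(model.contact_spheres):
        i = model.segment_index(sph.segment)
        loc = np.asarray(sph.location)
        r = _rot(kin.phi[i]) @ loc
        p = kin.origin[i] + r
        pv = kin.origin_vel[i] + kin.omega[i] * _perp(r)
        out[k] = hunt_crossley_force(sph, p, pv)
    return out


def contact_grf(model: ModelSpec, state: GeneralizedState):
    """Contact forces: per-sphere array, per-foot planar sums, base wrench.

    Returns ``(per_sphere, per_foot, wrench)`` where ``per_foot`` maps foot
    segment name to its summed (anterior-posterior, vertical) force and
    ``wrench`` is the equivalent (fx, fy, moment about the base origin).
    """
    per_sphere = sphere_forces(model, state)
    kin = forward_kinematics(model, state.q, state.v)
    per_foot = {f: np.zeros(2, dtype=per_sphere.dtype) for f in model.feet}
    wrench = np.zeros(3, dtype=per_sphere.dtype)
    for k, sph in enumerate(model.contact_spheres):
        i = model.segment_index(sph.segment)
        p = kin.origin[i] + _rot(kin.phi[i]) @ np.asarray(sph.location)
        f = per_sphere[k]
        foot = sph.segment
        per_foot[foot] = per_foot[foot] + f
        arm = p - kin.origin[0]
        wrench[:2] += f
        wrench[2] += arm[0] * f[1] - arm[1] * f[0]
    return per_sphere, per_foot, wrench


def mtp_spring_moment(q_mtp, stiffness, neutral_angle=0.0):
    """Linear MTP spring moment ``-k (q - neutral)`` in N m."""
    return -stiffness * (q_mtp - neutral_angle)


def mtp_spring_torques(model: ModelSpec, q) -> np.ndarray:
    """Spring moment vector over internal DOFs (zeros except MTP joints)."""
    q = np.asarray(q)
    tau = np.zeros(model.nq - _BASE_DOFS, dtype=q.dtype)
    for name in model.mtp_joints:
        i = model.dof_index(name) - _BASE_DOFS
        tau[i] = mtp_spring_moment(
            q[model.dof_index(name)], model.mtp_spring_stiffness, model.mtp_neutral_angle
        )
    return tau


def aerodynamic_drag(com_velocity_x, params: DragParams):
    """Horizontal drag force opposing CoM motion: -0.5 rho Cd Af v |v|."""
    v = com_velocity_x
    speed = np.sqrt(v * v + 1e-16)
    return -0.5 * params.air_density * params.drag_coefficient * params.frontal_area * v * speed


def com_state(model: ModelSpec, state: GeneralizedState):
    """Whole-body CoM position and velocity (mass-weighted, exact)."""
    kin = forward_kinematics(model, state.q, state.v)
    m = np.array([s.mass for s in model.segments])
    pos = (m[:, None] * kin.com).sum(axis=0) / model.total_mass
    vel = (m[:, None] * kin.com_vel).sum(axis=0) / model.total_mass
    return pos, vel


# ----------------------------------------------------------------------
# default planar sprinter model


def default_model(
    body_mass: float = 72.2,
    stature: float = 1.79,
    include_mtp: bool = False,
    actuator_map: dict[str, str] | None = None,
) -> ModelSpec:
    """Nine-segment planar sprinter (trunk+head lumped, pelvis, two legs).

    Segment masses, lengths and inertias follow standard anthropometric
    fractions scaled to ``body_mass`` and ``stature``; the trunk segment
    absorbs the arms and head so total mass is exact. With
    ``include_mtp=True`` each foot splits into rearfoot + forefoot joined
    by an MTP joint carrying a linear spring.
    """
    M, H = body_mass, stature
    l_thigh = 0.245 * H
    l_shank = 0.246 * H
    l_foot = 0.152 * H
    l_trunk = 0.30 * H
    m_pelvis = 0.117 * M
    m_thigh = 0.100 * M
    m_shank = 0.0465 * M
    m_foot = 0.0145 * M
    m_trunk = M - m_pelvis - 2 * (m_thigh + m_shank + m_foot)

    def rod_inertia(m, L, rg=0.30):
        return m * (rg * L) ** 2

    ankle_h = 0.08  # ankle joint height above the sole
    sph_r = 0.02
    sole_y = -(ankle_h - sph_r)  # sphere centres, foot frame

    segments = [
        Segment("pelvis", m_pelvis, rod_inertia(m_pelvis, 0.2, 0.45), 0.2, (0.0, 0.0)),
        Segment("trunk", m_trunk, rod_inertia(m_trunk, l_trunk * 1.6, 0.55), l_trunk * 1.6, (0.0, 0.30)),
        Segment("thigh_r", m_thigh, rod_inertia(m_thigh, l_thigh), l_thigh, (0.0, -0.433 * l_thigh)),
        Segment("shank_r", m_shank, rod_inertia(m_shank, l_shank), l_shank, (0.0, -0.433 * l_shank)),
        Segment("thigh_l", m_thigh, rod_inertia(m_thigh, l_thigh), l_thigh, (0.0, -0.433 * l_thigh)),
        Segment("shank_l", m_shank, rod_inertia(m_shank, l_shank), l_shank, (0.0, -0.433 * l_shank)),
    ]
    joints = [
        Joint("lumbar", "pelvis", "trunk", (0.0, 0.07)),
        Joint("hip_r", "pelvis", "thigh_r", (0.0, -0.07)),
        Joint("knee_r", "thigh_r", "shank_r", (0.0, -l_thigh)),
        Joint("hip_l", "pelvis", "thigh_l", (0.0, -0.07)),
        Joint("knee_l", "thigh_l", "shank_l", (0.0, -l_thigh)),
    ]
    spheres = []
    mtp_joints = []
    if include_mtp:
        m_rear, m_fore = 0.65 * m_foot, 0.35 * m_foot
        for side in ("r", "l"):
            segments += [
                Segment(f"foot_{side}", m_rear, rod_inertia(m_rear, 0.6 * l_foot), 0.6 * l_foot, (0.03, -0.04)),
                Segment(f"forefoot_{side}", m_fore, rod_inertia(m_fore, 0.4 * l_foot, 0.4), 0.4 * l_foot, (0.03, 0.0)),
            ]
            joints += [
                Joint(f"ankle_{side}", f"shank_{side}", f"foot_{side}", (0.0, -l_shank)),
                Joint(f"mtp_{side}", f"foot_{side}", f"forefoot_{side}", (0.55 * l_foot, sole_y)),
            ]
            spheres += [
                ContactSphereParams(f"foot_{side}", (-0.25 * l_foot, sole_y), sph_r),
                ContactSphereParams(f"forefoot_{side}", (0.30 * l_foot, 0.0), sph_r),
            ]
            mtp_joints.append(f"mtp_{side}")
    else:
        for side in ("r", "l"):
            segments.append(
                Segment(f"foot_{side}", m_foot, rod_inertia(m_foot, l_foot, 0.35), l_foot, (0.35 * l_foot, -0.04))
            )
            joints.append(Joint(f"ankle_{side}", f"shank_{side}", f"foot_{side}", (0.0, -l_shank)))
            spheres += [
                ContactSphereParams(f"foot_{side}", (-0.25 * l_foot, sole_y), sph_r),
                ContactSphereParams(f"foot_{side}", (0.70 * l_foot, sole_y), sph_r),
            ]

    # Samozino-style drag defaults: frontal area from stature and mass
    Af = 0.266 * (0.2025 * H ** 0.725 * M ** 0.425)
    drag = DragParams(air_density=1.2, drag_coefficient=0.9, frontal_area=Af)
    return ModelSpec(
        segments,
        joints,
        contact_spheres=spheres,
        drag=drag,
        mtp_joints=mtp_joints,
        actuator_map=actuator_map,
    )


# ----------------------------------------------------------------------
# batched evaluation (vectorized over a leading axis)
#
# The optimal-control layer evaluates the dynamics residual at every
# collocation point and for every complex-step perturbation direction;
# these batched twins of the scalar routines perform all of that in a
# handful of numpy calls.


def _fk_batch(model: ModelSpec, q, v, vdot=None):
    """Forward kinematics for a batch of states; q, v, vdot: (B, nq).

    Returns dict of arrays: origin/origin_vel (B, nseg, 2), phi/omega
    (B, nseg), com/com_vel[/com_acc] (B, nseg, 2), alpha (B, nseg),
    pivot (B, nq, 2).
    """
    q = np.asarray(q)
    v = np.asarray(v)
    B = q.shape[0]
    n = len(model.segments)
    dt = np.result_type(q, v, float)
    origin = np.zeros((B, n, 2), dtype=dt)
    ovel = np.zeros((B, n, 2), dtype=dt)
    phi = np.zeros((B, n), dtype=dt)
    omega = np.zeros((B, n), dtype=dt)
    com = np.zeros((B, n, 2), dtype=dt)
    cvel = np.zeros((B, n, 2), dtype=dt)
    pivot = np.zeros((B, model.nq, 2), dtype=dt)
    if vdot is not None:
        vdot = np.asarray(vdot)
        oacc = np.zeros((B, n, 2), dtype=dt)
        alpha = np.zeros((B, n), dtype=dt)
        cacc = np.zeros((B, n, 2), dtype=dt)
    else:
        oacc = alpha = cacc = None

    origin[:, 0] = q[:, :2]
    ovel[:, 0] = v[:, :2]
    phi[:, 0] = q[:, 2]
    omega[:, 0] = v[:, 2]
    if vdot is not None:
        oacc[:, 0] = vdot[:, :2]
        alpha[:, 0] = vdot[:, 2]
    pivot[:, 2] = origin[:, 0]

    def rotv(c, s, vec):
        return np.stack([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]], axis=-1)

    for i, seg in enumerate(model.segments):
        if i > 0:
            j = model._parent_joint[i]
            p = model.segment_index(j.parent)
            jd = _BASE_DOFS + model.joints.index(j)
            cp, sp_ = np.cos(phi[:, p]), np.sin(phi[:, p])
            r = rotv(cp, sp_, np.asarray(j.location))
            rperp = np.stack([-r[..., 1], r[..., 0]], axis=-1)
            origin[:, i] = origin[:, p] + r
            ovel[:, i] = ovel[:, p] + omega[:, p, None] * rperp
            phi[:, i] = phi[:, p] + q[:, jd]
            omega[:, i] = omega[:, p] + v[:, jd]
            if vdot is not None:
                oacc[:, i] = (
                    oacc[:, p]
                    + alpha[:, p, None] * rperp
                    - (omega[:, p] ** 2)[:, None] * r
                )
                alpha[:, i] = alpha[:, p] + vdot[:, jd]
            pivot[:, jd] = origin[:, i]
        ci, si = np.cos(phi[:, i]), np.sin(phi[:, i])
        rc = rotv(ci, si, np.asarray(seg.com_offset))
        rcperp = np.stack([-rc[..., 1], rc[..., 0]], axis=-1)
        com[:, i] = origin[:, i] + rc
        cvel[:, i] = ovel[:, i] + omega[:, i, None] * rcperp
        if vdot is not None:
            cacc[:, i] = (
                oacc[:, i]
                + alpha[:, i, None] * rcperp
                - (omega[:, i] ** 2)[:, None] * rc
            )
    return {
        "origin": origin, "origin_vel": ovel, "phi": phi, "omega": omega,
        "com": com, "com_vel": cvel, "com_acc": cacc, "alpha": alpha,
        "pivot": pivot,
    }


def _com_jacobians_batch(model: ModelSpec, kin):
    """Translational CoM Jacobians, (B, nseg, 2, nq)."""
    com = kin["com"]
    pivot = kin["pivot"]
    B, n, _ = com.shape
    J = np.zeros((B, n, 2, model.nq), dtype=com.dtype)
    J[:, :, 0, 0] = 1.0
    J[:, :, 1, 1] = 1.0
    for i in range(n):
        for jd in model._rot_ancestors[i]:
            d = com[:, i] - pivot[:, jd]
            J[:, i, 0, jd] = -d[:, 1]
            J[:, i, 1, jd] = d[:, 0]
    return J


def inverse_dynamics_batch(model: ModelSpec, q, v, vdot):
    """Batched ID(q, v, a) = M a + C + G, shape (B, nq)."""
    kin = _fk_batch(model, q, v, vdot)
    J = _com_jacobians_batch(model, kin)
    g = np.array([0.0, -model.gravity])
    out = np.zeros((q.shape[0], model.nq), dtype=J.dtype)
    for i, seg in enumerate(model.segments):
        f = seg.mass * (kin["com_acc"][:, i] - g)  # (B, 2)
        out += np.einsum("bxq,bx->bq", J[:, i], f)
        for jd in model._rot_ancestors[i]:
            out[:, jd] += seg.inertia * kin["alpha"][:, i]
    return out


def sphere_positions_batch(model: ModelSpec, kin):
    """Contact-sphere centre positions and velocities, (B, nsph, 2)."""
    nsph = len(model.contact_spheres)
    B = kin["phi"].shape[0]
    pos = np.zeros((B, nsph, 2), dtype=kin["com"].dtype)
    vel = np.zeros_like(pos)
    for k, sph in enumerate(model.contact_spheres):
        i = model.segment_index(sph.segment)
        c, s = np.cos(kin["phi"][:, i]), np.sin(kin["phi"][:, i])
        loc = np.asarray(sph.location)
        r = np.stack([c * loc[0] - s * loc[1], s * loc[0] + c * loc[1]], axis=-1)
        rperp = np.stack([-r[:, 1], r[:, 0]], axis=-1)
        pos[:, k] = kin["origin"][:, i] + r
        vel[:, k] = kin["origin_vel"][:, i] + kin["omega"][:, i, None] * rperp
    return pos, vel


def sphere_forces_batch(model: ModelSpec, kin):
    """Batched smooth Hunt-Crossley forces, (B, nsph, 2)."""
    pos, vel = sphere_positions_batch(model, kin)
    B, nsph, _ = pos.shape
    out = np.zeros((B, nsph, 2), dtype=pos.dtype)
    for k, sph in enumerate(model.contact_spheres):
        pen = sph.radius - pos[:, k, 1]
        pen_rate = -vel[:, k, 1]
        pen_s = softplus(pen, sph.penetration_smoothing)
        bracket = smooth_pos(1.0 + sph.dissipation * pen_rate, 0.05)
        fn = sph.stiffness * pen_s ** 1.5 * bracket
        ft = -sph.friction * fn * np.tanh(vel[:, k, 0] / sph.velocity_smoothing)
        out[:, k, 0] = ft
        out[:, k, 1] = fn
    return out


def external_generalized_batch(model: ModelSpec, kin, per_sphere, drag_force):
    """Generalized forces of contact + CoM drag, (B, nq).

    ``drag_force``: (B, 2) planar force applied at the whole-body CoM.
    """
    pos, _ = sphere_positions_batch(model, kin)
    B = pos.shape[0]
    out = np.zeros((B, model.nq), dtype=pos.dtype)
    for k, sph in enumerate(model.contact_spheres):
        i = model.segment_index(sph.segment)
        f = per_sphere[:, k]
        out[:, 0] += f[:, 0]
        out[:, 1] += f[:, 1]
        for jd in model._rot_ancestors[i]:
            arm = pos[:, k] - kin["pivot"][:, jd]
            out[:, jd] += arm[:, 0] * f[:, 1] - arm[:, 1] * f[:, 0]
    masses = np.array([s.mass for s in model.segments])
    com = np.einsum("s,bsx->bx", masses, kin["com"]) / model.total_mass
    Jc = _com_jacobians_batch(model, kin)
    Jcom = np.einsum("s,bsxq->bxq", masses, Jc) / model.total_mass
    out += np.einsum("bxq,bx->bq", Jcom, drag_force)
    return out


def com_state_batch(model: ModelSpec, kin):
    """Whole-body CoM position and velocity, each (B, 2)."""
    masses = np.array([s.mass for s in model.segments])
    pos = np.einsum("s,bsx->bx", masses, kin["com"]) / model.total_mass
    vel = np.einsum("s,bsx->bx", masses, kin["com_vel"]) / model.total_mass
    return pos, vel


def model_to_dict(model: ModelSpec) -> dict:
    """Serialize a ModelSpec to a plain dictionary (YAML/JSON friendly)."""
    return {
        "gravity": model.gravity,
        "mtp_spring_stiffness": model.mtp_spring_stiffness,
        "mtp_neutral_angle": model.mtp_neutral_angle,
        "mtp_joints": list(model.mtp_joints),
        "segments": [
            {"name": s.name, "mass": s.mass, "inertia": s.inertia,
             "length": s.length, "com_offset": list(s.com_offset)}
            for s in model.segments
        ],
        "joints": [
            {"name": j.name, "parent": j.parent, "child": j.child,
             "location": list(j.location)}
            for j in model.joints
        ],
        "contact_spheres": [
            {"segment": c.segment, "location": list(c.location), "radius": c.radius,
             "stiffness": c.stiffness, "dissipation": c.dissipation,
             "friction": c.friction, "velocity_smoothing": c.velocity_smoothing,
             "penetration_smoothing": c.penetration_smoothing}
            for c in model.contact_spheres
        ],
        "drag": {"air_density": model.drag.air_density,
                 "drag_coefficient": model.drag.drag_coefficient,
                 "frontal_area": model.drag.frontal_area},
        "actuator_map": dict(model.actuator_map),
    }


def model_from_dict(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from the dictionary schema of ``model_to_dict``.

    All quantities are SI: masses kg, lengths m, inertias kg m^2, angles
    rad, stiffnesses N/m^1.5 (contact) or N m/rad (MTP springs).
    """
    segments = [Segment(d["name"], d["mass"], d["inertia"], d["length"],
                        tuple(d["com_offset"])) for d in cfg["segments"]]
    joints = [Joint(d["name"], d["parent"], d["child"], tuple(d["location"]))
              for d in cfg["joints"]]
    spheres = [ContactSphereParams(
        d["segment"], tuple(d["location"]), d["radius"],
        d.get("stiffness", 3.0e6), d.get("dissipation", 2.0),
        d.get("friction", 0.8), d.get("velocity_smoothing", 0.05),
        d.get("penetration_smoothing", 1.0e-4),
    ) for d in cfg.get("contact_spheres", [])]
    drag_cfg = cfg.get("drag", {})
    return ModelSpec(
        segments, joints,
        gravity=cfg.get("gravity", 9.80665),
        contact_spheres=spheres,
        drag=DragParams(**drag_cfg) if drag_cfg else None,
        mtp_joints=cfg.get("mtp_joints"),
        mtp_spring_stiffness=cfg.get("mtp_spring_stiffness", 25.0),
        mtp_neutral_angle=cfg.get("mtp_neutral_angle", 0.0),
        actuator_map=cfg.get("actuator_map"),
    )
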