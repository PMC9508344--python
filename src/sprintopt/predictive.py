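"""Predictive "free-moment" optimal control simulations.

Starting from a solved data-tracking simulation, each predictive problem
frees a chosen subset of the sagittal net joint moments (ankle, knee
and/or hip, both legs) while the remaining net moments are tracked
against the tracking solution, and minimizes the horizon duration. Seven
configurations are studied: each single joint freed (A-free, K-free,
H-free), each pair (A-K-free, A-H-free, K-H-free) and all three
(A-K-H-free).

The objective is J = W1*tf + moment-tracking + effort + control terms,
with the moment deviations normalized by 2% of each moment's range in
the tracking solution ("a permissible error of 5 Nm assuming a 250 Nm
range"). Boundary constraints pin the initial multibody state and the
terminal pelvis anterior-posterior displacement to the tracking values,
and keep terminal relative joint angles within +-10 degrees of the
tracking posture; the free horizon may shrink by at most 5%.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import collocation as coll
from .model import ModelSpec
from .muscle import ActivationParams, HillCurves, MTUParams
from .tracking import (
    ACT_RATE_BOUND,
    FT_RATE_BOUND,
    RESERVE_BOUND,
    RESERVE_BOUND_MTP,
    TrackingResult,
    _Layout,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictiveWeights",
    "MomentMask",
    "build_mask",
    "FREE_MOMENT_CONFIGS",
    "boundary_constraint_set",
    "build_predictive_ocp",
    "run_predictive",
    "run_suite",
    "PredictiveResult",
]

FREE_MOMENT_CONFIGS = (
    "A-free", "K-free", "H-free", "A-K-free", "A-H-free", "K-H-free", "A-K-H-free",
)
_ALIASES = {
    "H-K-free": "K-H-free",
    "H-A-free": "A-H-free",
    "K-A-free": "A-K-free",
    "none": "none",
}
_JOINT_PREFIX = {"A": "ankle", "K": "knee", "H": "hip"}


@dataclass
class PredictiveWeights:
    """Objective weights W1..W6 (time, moment tracking, effort, reserves,
    accelerations, muscle-state rates)."""

    W1: float = 50.0
    W2: float = 0.1
    W3: float = 0.01
    W4: float = 1.0
    W5: float = 0.0001
    W6: float = 0.1

    def __post_init__(self):
        if min(self.W1, self.W2, self.W3, self.W4, self.W5, self.W6) < 0:
            raise ValueError("weights must be >= 0")


@dataclass
class MomentMask:
    """Binary tracked/freed mask over the internal net joint moments."""

    name: str
    tracked: np.ndarray  # 1 = tracked, 0 = freed

    @property
    def freed_indices(self):
        return np.where(self.tracked == 0)[0]


def build_mask(config_name: str, model: ModelSpec) -> MomentMask:
    """Mask for a named configuration: zeros exactly at the freed sagittal
    ankle/knee/hip moment indices of both legs, ones elsewhere."""
    name = _ALIASES.get(config_name, config_name)
    tracked = np.ones(len(model.internal_dofs))
    if name == "none":
        return MomentMask("none", tracked)
    if name not in FREE_MOMENT_CONFIGS:
        raise ValueError(f"unknown free-moment configuration {config_name!r}")
    letters = name.replace("-free", "").split("-")
    for letter in letters:
        joint = _JOINT_PREFIX[letter]
        for side in ("r", "l"):
            dof = f"{joint}_{side}"
            if dof not in model.internal_dofs:
                raise ValueError(f"model lacks DOF {dof} for configuration {name}")
            tracked[model.internal_dofs.index(dof)] = 0.0
    return MomentMask(name, tracked)


@dataclass
class BoundaryConstraints:
    """Targets extracted from the tracking solution."""

    x0: np.ndarray  # initial multibody state (q, v)
    pelvis_x_end: float
    joint_angles_end: np.ndarray  # terminal relative joint angles
    window_rad: float
    tf_bounds: tuple[float, float]


def boundary_constraint_set(track: TrackingResult, model: ModelSpec,
                            window_deg: float = 10.0,
                            tf_shrink: float = 0.05) -> BoundaryConstraints:
    """Boundary targets: equality on the initial multibody state, equality
    on terminal pelvis forward displacement, a +-window on terminal
    relative joint angles, and the horizon bounds [ (1-shrink)*tf, tf ]."""
    sol = track.solution
    layout = track.layout
    x0 = sol.states[0, 0, : 2 * model.nq].copy()
    xf = sol.states[-1, -1]
    ix = model.dof_index("base_x")
    jidx = [model.dof_index(d) for d in model.internal_dofs]
    return BoundaryConstraints(
        x0=x0,
        pelvis_x_end=float(xf[ix]),
        joint_angles_end=xf[jidx].copy(),
        window_rad=np.radians(window_deg),
        tf_bounds=((1.0 - tf_shrink) * sol.t_final, sol.t_final),
    )


def build_predictive_ocp(
    track: TrackingResult,
    model: ModelSpec,
    mask: MomentMask,
    mesh_n: int | None = None,
    d: int = 3,
    weights: PredictiveWeights | None = None,
    muscles: list[MTUParams] | None = None,
    curves: HillCurves | None = None,
    act_params: ActivationParams | None = None,
    window_deg: float = 10.0,
    tf_shrink: float = 0.05,
    fix_tf: bool = False,
):
    """Assemble the predictive OCP for one free-moment configuration.

    The tracking solution provides the reference moments (interpolated on
    normalized time, stretch-to-fit when the predictive horizon differs),
    the initial guess for all states and controls, the bounds (identical
    to the tracking problem's), and the boundary targets.
    """
    from .tracking import build_tracking_ocp  # layout/bounds helpers share code

    W = weights or PredictiveWeights()
    layout = track.layout
    prep = track.prep
    tf_track = track.solution.t_final
    N = mesh_n or track.solution.mesh.n_intervals
    mesh = coll.Mesh(
        N, d,
        (tf_track, tf_track) if fix_tf
        else ((1.0 - tf_shrink) * tf_track, tf_track),
    )
    # rebuild the tracking OCP machinery to reuse its bounds and path
    base_ocp, _, layout, norms = build_tracking_ocp(
        prep, model, coll.Mesh(N, d, tf_track), muscles=muscles,
        curves=curves, act_params=act_params,
    )

    # reference moments on normalized time from the tracking solution
    sig_dense = np.linspace(0.0, 1.0, 4 * N + 1)
    tau_ref = track.moments_series(sig_dense * tf_track)
    from scipy.interpolate import make_interp_spline

    tau_ref_spl = make_interp_spline(sig_dense, tau_ref, k=3)
    rng = np.ptp(tau_ref, axis=0)
    tau_norm = np.maximum(0.02 * rng, 0.5)  # 2% of tracking range, floored
    tracked_idx = np.where(mask.tracked == 1)[0]

    bc = boundary_constraint_set(track, model, window_deg, tf_shrink)
    res_b = np.array([
        RESERVE_BOUND_MTP if dd in model.mtp_joints else RESERVE_BOUND
        for dd in model.internal_dofs
    ])
    accel_norm = norms.accel
    fmax = np.array([p.fmax for p in layout.muscles]) if layout.nm else np.zeros(0)
    fmax_w = np.sqrt(W.W3 * fmax / fmax.sum()) if layout.nm else fmax
    _net_moments = _net_moments_factory(model, layout)

    def quad_batch(X, U, sigma, TF):
        tau = _net_moments(X, U)
        ref = tau_ref_spl(np.real(sigma))
        r_mom = np.sqrt(W.W2) * ((ref - tau)[:, tracked_idx] / tau_norm[tracked_idx])
        r_res = np.sqrt(W.W4) * U[:, layout.sl_res] / res_b
        r_acc = np.sqrt(W.W5) * U[:, layout.sl_vdot] / accel_norm
        parts = [r_mom, r_res, r_acc]
        if layout.nm:
            parts.append(fmax_w * X[:, layout.sl_a])
            parts.append(np.sqrt(W.W6) * U[:, layout.sl_ftdot] / FT_RATE_BOUND)
            parts.append(np.sqrt(W.W6) * U[:, layout.sl_adot] / ACT_RATE_BOUND)
        return np.concatenate(parts, axis=1)

    def quad_residuals(x, u, sigma, tf_val):
        return quad_batch(x[None, :], u[None, :], np.array([sigma]),
                          np.array([tf_val]))[0]

    def mayer(x0, xf, tf_val):
        return W.W1 * tf_val

    def mayer_terms(x0, xf, tf_val):
        return {"time": float(np.real(W.W1 * tf_val))}

    ix = model.dof_index("base_x")
    jidx = np.array([model.dof_index(dd) for dd in model.internal_dofs])
    nq2 = 2 * model.nq

    def boundary(x0, xf, tf_val):
        return np.concatenate([
            x0[:nq2] - bc.x0,
            [xf[ix] - bc.pelvis_x_end],
            xf[jidx] - bc.joint_angles_end,
        ])

    nb = nq2 + 1 + len(jidx)
    b_lb = np.concatenate([np.zeros(nq2 + 1), np.full(len(jidx), -bc.window_rad)])
    b_ub = np.concatenate([np.zeros(nq2 + 1), np.full(len(jidx), bc.window_rad)])

    off = len(tracked_idx)
    term_slices = {"tracking_moments": slice(0, off)}
    term_slices["control_reserves"] = slice(off, off + layout.n_int)
    off += layout.n_int
    term_slices["control_accelerations"] = slice(off, off + model.nq)
    off += model.nq
    if layout.nm:
        term_slices["effort"] = slice(off, off + layout.nm)
        off += layout.nm
        term_slices["control_muscle_rates"] = slice(off, off + 2 * layout.nm)
        off += 2 * layout.nm

    ocp = coll.OCPDefinition(
        nx=base_ocp.nx,
        nu=base_ocp.nu,
        A_x=base_ocp.A_x,
        A_u=base_ocp.A_u,
        x_lb=base_ocp.x_lb,
        x_ub=base_ocp.x_ub,
        u_lb=base_ocp.u_lb,
        u_ub=base_ocp.u_ub,
        path=base_ocp.path,
        path_batch=base_ocp.path_batch,
        path_lb=base_ocp.path_lb,
        path_ub=base_ocp.path_ub,
        path_scale=base_ocp.path_scale,
        boundary=boundary,
        boundary_lb=b_lb,
        boundary_ub=b_ub,
        quad_residuals=quad_residuals,
        quad_batch=quad_batch,
        n_quad=off,
        mayer=mayer,
        mayer_terms=mayer_terms,
        term_slices=term_slices,
    )

    # initial guess: the tracking solution resampled onto this mesh
    guess = _guess_from_tracking(track, mesh, layout)
    return ocp, mesh, guess, mask


def _net_moments_factory(model: ModelSpec, layout: _Layout):
    from .muscle import mtu_geometry

    def _net_moments(X, U):
        q = X[:, layout.sl_q]
        tau = U[:, layout.sl_act] * layout.torque_mask + U[:, layout.sl_res]
        tau = tau.astype(np.result_type(X, U))
        for name in model.mtp_joints:
            j = model.internal_dofs.index(name)
            tau[:, j] = tau[:, j] - model.mtp_spring_stiffness * (
                q[:, model.dof_index(name)] - model.mtp_neutral_angle
            )
        if layout.nm:
            qd = {dd: q[:, model.dof_index(dd)] for dd in model.internal_dofs}
            ft = X[:, layout.sl_ft]
            for m_i, p in enumerate(layout.muscles):
                _, _, arms = mtu_geometry(qd, p)
                for dof, r in arms.items():
                    j = model.internal_dofs.index(dof)
                    tau[:, j] = tau[:, j] + ft[:, m_i] * p.fmax * r
        return tau

    return _net_moments


def _guess_from_tracking(track: TrackingResult, mesh: coll.Mesh, layout):
    sol = track.solution
    tf = sol.t_final
    starts, colls = mesh.normalized_times()
    states = np.zeros((mesh.n_intervals, mesh.d + 1, layout.nx))
    controls = np.zeros((mesh.n_intervals, layout.nu))
    for i in range(mesh.n_intervals):
        pts = np.concatenate([[starts[i]], colls[i]]) * tf
        states[i] = sol.interpolate(pts)
        controls[i] = sol.control_at(np.array([starts[i] * tf]))[0]
    return states, controls, tf


@dataclass
class PredictiveResult:
    config: str
    solution: coll.OCPSolution
    mask: MomentMask
    layout: _Layout
    solve_seconds: float = 0.0

    def moments_series(self, times):
        xs = self.solution.interpolate(times)
        us = self.solution.control_at(times)
        net = _net_moments_factory(self.layout.model, self.layout)
        return np.real(net(xs, us))

    def summary(self) -> dict:
        s = self.solution
        return {
            "config": self.config,
            "status": s.status,
            "success": s.success,
            "objective": s.objective,
            "breakdown": {k: float(v) for k, v in s.breakdown.items()},
            "t_final": s.t_final,
            "iterations": s.n_iter,
            "constraint_violation": s.constr_violation,
            "solve_seconds": self.solve_seconds,
        }


def run_predictive(
    config_name: str,
    track: TrackingResult,
    model: ModelSpec,
    mesh_n: int | None = None,
    d: int = 3,
    weights: PredictiveWeights | None = None,
    muscles: list[MTUParams] | None = None,
    tol: float = 1e-3,
    maxiter: int = 120,
    fix_tf: bool = False,
    window_deg: float = 10.0,
) -> PredictiveResult:
    """Solve one predictive free-moment simulation."""
    mask = build_mask(config_name, model)
    ocp, mesh, guess, mask = build_predictive_ocp(
        track, model, mask, mesh_n=mesh_n, d=d, weights=weights,
        muscles=muscles, fix_tf=fix_tf, window_deg=window_deg,
    )
    tr = coll.transcribe(ocp, mesh)
    t0 = time.time()
    sol = coll.solve(tr, guess, tol=tol, maxiter=maxiter)
    dt_solve = time.time() - t0
    logger.info(
        "predictive %s: status %s, tf %.4f s (track %.4f), objective %.4f, %d it, %.1f s",
        mask.name, sol.status, sol.t_final, track.solution.t_final,
        sol.objective, sol.n_iter, dt_solve,
    )
    return PredictiveResult(mask.name, sol, mask, track.layout, dt_solve)


def run_suite(
    track: TrackingResult,
    model: ModelSpec,
    configs=FREE_MOMENT_CONFIGS,
    **kwargs,
) -> dict[str, PredictiveResult]:
    """Run all requested free-moment configurations with identical settings.

    Individual failures are recorded (the failing configuration's result
    carries its non-success status) and the suite continues.
    """
    out = {}
    for name in configs:
        try:
            out[name] = run_predictive(name, track, model, **kwargs)
        except Exception as e:  # noqa: BLE001 - record and continue
            logger.error("predictive %s failed: %s", name, e)
            out[name] = None
    return out
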