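"""Performance and technique outcome measures for sprint simulations.

Implements the quantities used to compare data-tracking and predictive
simulations: average horizontal external power (rate of change of
horizontal CoM kinetic energy), trapezoidal anterior-posterior impulses
split into net/propulsive/braking, stance detection and durations,
touchdown and take-off technique variables, the trunk-to-thigh angle with
its front-side/back-side classification, and peak net joint moments with
their timing in stance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelSpec, GeneralizedState, forward_kinematics, com_state, _rot

__all__ = [
    "average_horizontal_power",
    "horizontal_impulses",
    "detect_stance",
    "touchdown_metrics",
    "takeoff_angles",
    "trunk_thigh_angle",
    "peak_moments",
    "percent_change",
    "OutcomeReport",
]

STANCE_THRESHOLD_N = 20.0  # vertical-GRF event threshold


def average_horizontal_power(mass: float, v0: float, vf: float, tf: float) -> float:
    """Average horizontal external power in W: (KEf - KE0) / tf.

    Uses horizontal CoM velocities only; vertical motion does not enter.
    """
    if tf <= 0:
        raise ValueError("tf must be > 0")
    return (0.5 * mass * vf**2 - 0.5 * mass * v0**2) / tf


def horizontal_impulses(grf_ap, time, window=None):
    """Net, propulsive and braking AP impulses (N s) by trapezoidal quadrature.

    ``window`` is an optional (t_start, t_end) pair restricting the series;
    propulsive integrates the positive part, braking the negative part, so
    net = propulsive + braking.
    """
    grf_ap = np.asarray(grf_ap, dtype=float)
    time = np.asarray(time, dtype=float)
    if grf_ap.shape != time.shape:
        raise ValueError("series and time grids differ in length")
    if window is not None:
        m = (time >= window[0] - 1e-12) & (time <= window[1] + 1e-12)
        if not np.any(m):
            raise ValueError("empty stance window")
        grf_ap, time = grf_ap[m], time[m]
    net = np.trapezoid(grf_ap, time)
    propulsive = np.trapezoid(np.maximum(grf_ap, 0.0), time)
    braking = np.trapezoid(np.minimum(grf_ap, 0.0), time)
    return float(net), float(propulsive), float(braking)


def detect_stance(grf_vertical, time, threshold: float = STANCE_THRESHOLD_N):
    """Maximal runs with vertical GRF >= threshold, as (touchdown, takeoff).

    Returns a (possibly empty) list of time windows in order.
    """
    grf_vertical = np.asarray(grf_vertical, dtype=float)
    time = np.asarray(time, dtype=float)
    on = grf_vertical >= threshold
    windows = []
    start = None
    for i, flag in enumerate(on):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            windows.append((float(time[start]), float(time[i - 1])))
            start = None
    if start is not None:
        windows.append((float(time[start]), float(time[-1])))
    return windows


def _foot_point(model: ModelSpec, state: GeneralizedState, foot: str):
    """Distal contact-sphere centroid of ``foot`` and its velocity."""
    kin = forward_kinematics(model, state.q, state.v)
    pts, vels = [], []
    for sph in model.contact_spheres:
        if sph.segment != foot and not (
            sph.segment.startswith("forefoot") and sph.segment.endswith(foot[-2:])
        ):
            continue
        i = model.segment_index(sph.segment)
        loc = np.asarray(sph.location)
        r = _rot(kin.phi[i]) @ loc
        pts.append(kin.origin[i] + r)
        vels.append(kin.origin_vel[i] + kin.omega[i] * np.array([-r[1], r[0]]))
    if not pts:
        raise ValueError(f"no contact spheres on segment {foot}")
    # distal = furthest forward in the foot frame: last listed sphere (toe)
    return pts[-1], vels[-1]


def touchdown_metrics(model: ModelSpec, state: GeneralizedState, foot: str):
    """Foot horizontal velocity and CoM-foot AP distance at touchdown.

    Positive distance means the foot (distal contact-sphere centroid) is
    ahead of the whole-body CoM.
    """
    p, v = _foot_point(model, state, foot)
    com, _ = com_state(model, state)
    return float(v[0]), float(p[0] - com[0])


def takeoff_angles(model: ModelSpec, state: GeneralizedState, side: str):
    """Take-off technique angles in degrees for leg ``side`` ("r" or "l").

    Returns (hip extension, knee flexion, thigh angle, trunk angle) with the
    sagittal conventions: hip flexion positive / extension negative, full
    knee extension 0 with flexion negative, and thigh/trunk measured from
    the global vertical with clockwise (extension / forward inclination)
    negative.
    """
    kin = forward_kinematics(model, state.q, state.v)
    hip = np.degrees(state.q[model.dof_index(f"hip_{side}")])
    knee = np.degrees(state.q[model.dof_index(f"knee_{side}")])
    thigh = np.degrees(kin.phi[model.segment_index(f"thigh_{side}")])
    trunk = np.degrees(kin.phi[model.segment_index("trunk")])
    return float(hip), float(knee), float(thigh), float(trunk)


def trunk_thigh_angle(thigh_deg: float, trunk_deg: float, neutral_band: float = 1.0):
    """Trunk-to-thigh angle (deg) and front-/back-side mechanics label.

    The angle is 180 + (thigh - trunk): above 180 deg the thigh stays in
    front of a line drawn parallel to the trunk (front-side mechanics),
    below 180 deg it has extended past it (back-side). Angles within
    ``neutral_band`` of 180 are labelled neutral.
    """
    for a in (thigh_deg, trunk_deg):
        if not -180.0 < a < 180.0:
            raise ValueError("segment angles must lie in (-180, 180) deg")
    angle = 180.0 + (thigh_deg - trunk_deg)
    if angle > 180.0 + neutral_band:
        label = "front-side"
    elif angle < 180.0 - neutral_band:
        label = "back-side"
    else:
        label = "neutral"
    return float(angle), label


def peak_moments(tau, time, window):
    """Signed extrema of a net joint moment within a stance window.

    Returns (peak_positive, peak_negative, timing_pos, timing_neg) with
    timings expressed as percent of stance from touchdown; ties are broken
    by the earliest occurrence.
    """
    tau = np.asarray(tau, dtype=float)
    time = np.asarray(time, dtype=float)
    m = (time >= window[0] - 1e-12) & (time <= window[1] + 1e-12)
    if not np.any(m):
        raise ValueError("window contains no samples")
    tw, tt = tau[m], time[m]
    dur = window[1] - window[0]
    i_max = int(np.argmax(tw))
    i_min = int(np.argmin(tw))
    t_pos = 100.0 * (tt[i_max] - window[0]) / dur if dur > 0 else 0.0
    t_neg = 100.0 * (tt[i_min] - window[0]) / dur if dur > 0 else 0.0
    return float(tw[i_max]), float(tw[i_min]), float(t_pos), float(t_neg)


def percent_change(new: float, old: float) -> float:
    """Percent change 100*(new/old - 1), rounded half-away-from-zero to 0.1."""
    if old == 0:
        raise ValueError("reference value must be nonzero")
    raw = 100.0 * (new / old - 1.0)
    return float(np.sign(raw) * np.floor(abs(raw) * 10 + 0.5) / 10)


@dataclass
class OutcomeReport:
    """Per-simulation outcome summary (see module docstring)."""

    label: str
    average_power_w: float
    terminal_com_velocity: float
    time_horizon: float
    stances: dict[str, dict] = field(default_factory=dict)
    takeoff: dict[str, dict] = field(default_factory=dict)
    peak_moments: dict[str, dict] = field(default_factory=dict)

    def to_dict(self):
        return {
            "label": self.label,
            "average_power_w": self.average_power_w,
            "terminal_com_velocity": self.terminal_com_velocity,
            "time_horizon": self.time_horizon,
            "stances": self.stances,
            "takeoff": self.takeoff,
            "peak_moments": self.peak_moments,
        }


def evaluate_ocp_result(model: ModelSpec, label: str, result, body_mass: float,
                        n_samples: int = 400) -> "OutcomeReport":
    """Outcome report for a solved tracking or predictive simulation.

    ``result`` is a TrackingResult or PredictiveResult: states are
    interpolated from the collocation solution, per-foot GRF comes from
    the GRF consistency controls, and net joint moments from the
    actuator/reserve/spring (and muscle) contributions.
    """
    sol = result.solution
    layout = result.layout
    t = np.linspace(0.0, sol.t_final, n_samples)
    xs = sol.interpolate(t)
    us = sol.control_at(t)
    nq = model.nq
    coords = xs[:, :nq]
    vels = xs[:, nq:2 * nq]
    grf = us[:, layout.sl_grf]
    grf_per_foot = {
        f: grf[:, 2 * i: 2 * i + 2] for i, f in enumerate(model.feet)
    }
    mom = result.moments_series(t)
    moments = {d: mom[:, j] for j, d in enumerate(model.internal_dofs)}
    sagittal = [d for d in model.internal_dofs
                if any(d.startswith(p) for p in ("ankle", "knee", "hip"))]
    return evaluate_solution(
        model, label, t, coords, vels, grf_per_foot, moments, body_mass, sagittal
    )


def evaluate_solution(model: ModelSpec, label: str, time, coords, vels, grf_per_foot,
                      moments, body_mass, dof_moment_names):
    """Full outcome report for one simulated trajectory.

    ``grf_per_foot`` maps foot segment name to an (n, 2) AP/vertical force
    array; ``moments`` maps internal DOF name to a series.
    """
    time = np.asarray(time, dtype=float)
    st0 = GeneralizedState(coords[0], vels[0])
    stf = GeneralizedState(coords[-1], vels[-1])
    _, v0 = com_state(model, st0)
    _, vf = com_state(model, stf)
    tf = float(time[-1] - time[0])
    report = OutcomeReport(
        label=label,
        average_power_w=average_horizontal_power(body_mass, v0[0], vf[0], tf),
        terminal_com_velocity=float(vf[0]),
        time_horizon=tf,
    )
    for foot, forces in grf_per_foot.items():
        windows = detect_stance(forces[:, 1], time)
        if not windows:
            continue
        # the stance of interest is the longest window for that foot
        win = max(windows, key=lambda w: w[1] - w[0])
        net, prop, brake = horizontal_impulses(forces[:, 0], time, win)
        i_td = int(np.searchsorted(time, win[0]))
        td_state = GeneralizedState(coords[i_td], vels[i_td])
        foot_v, dist = touchdown_metrics(model, td_state, foot)
        i_to = int(np.searchsorted(time, win[1]))
        to_state = GeneralizedState(coords[min(i_to, len(time) - 1)], vels[min(i_to, len(time) - 1)])
        side = foot[-1]
        hip, knee, thigh, trunk = takeoff_angles(model, to_state, side)
        tta, lab = trunk_thigh_angle(thigh, trunk)
        report.stances[foot] = {
            "window": list(win),
            "duration": win[1] - win[0],
            "net_impulse": net,
            "propulsive_impulse": prop,
            "braking_impulse": brake,
            "touchdown_foot_velocity": foot_v,
            "touchdown_com_foot_distance": dist,
        }
        report.takeoff[foot] = {
            "hip_extension_deg": hip,
            "knee_flexion_deg": knee,
            "thigh_angle_deg": thigh,
            "trunk_angle_deg": trunk,
            "trunk_thigh_angle_deg": tta,
            "mechanics": lab,
        }
        for dof in dof_moment_names:
            pk_pos, pk_neg, tp, tn = peak_moments(moments[dof], time, win)
            # positive direction is hip flexion / knee extension / ankle
            # dorsiflexion under the CCW-positive sagittal convention
            report.peak_moments.setdefault(foot, {})[dof] = {
                "peak_positive": pk_pos,
                "peak_negative": pk_neg,
                "timing_positive_pct": tp,
                "timing_negative_pct": tn,
            }
    return report
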