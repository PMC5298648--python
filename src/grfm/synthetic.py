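"""Synthetic walking trials with exactly known ground truth.

The generator builds a 16-segment body whose summed Newton-Euler wrench equals
a prescribed analytic total ground-reaction wrench, together with heel/toe
point trajectories that cross the event-detection velocity thresholds at known
sample-aligned times, and per-foot ground-truth wrenches obtained by applying
a chosen set of smooth-transition curves to the total.  Every quantity is an
exact closed-form derivative of the corresponding position, so the pipeline
can be verified to machine precision without recorded data.

Construction
------------
Segments translate with the whole-body trajectory (constant orientations);
left/right limb swing is antisymmetric within pairs of equal mass, which
leaves the total force untouched and contributes a single analytic transverse
moment term that is folded into the ground truth.  The total force is a
body-weight-scaled constant plus sinusoids at step and stride frequency whose
double integral defines the CoM path.  Event times sit on the sample grid and
the trapezoidal heel/toe speed profiles cross the 0.6/1.9 pelvis-speed
thresholds half a sample before each event, so threshold detection lands
exactly on the ground-truth sample.

A separate analytic pendulum-chain construction exercises the rotational terms
of Euler's equation; its linear and angular momenta are available in closed
form for momentum-derivative oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import (
    BodyModel,
    ScaledSegment,
    default_instrumentation,
    load_deleva_table,
    scale_body,
    segment_inertia,
)
from .distribution import STAFunction, default_sta
from .dynamics import WrenchSeries
from .errors import NumericalError
from .events import FootEvents, GaitEventTable
from .kinematics import (
    FramePair,
    PointTrajectory,
    SegmentKinematics,
    SegmentKinematicsSeries,
    walking_frame,
)

QUAT_DOWN = np.array([0.0, 1.0, 0.0, 0.0])  # longitudinal axis points down
QUAT_FORWARD = np.array([np.sqrt(0.5), 0.0, np.sqrt(0.5), 0.0])  # points along +x
QUAT_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def default_segment_lengths(height_m: float) -> dict[str, float]:
    """Segment lengths as standing-height fractions (package defaults)."""
    fractions = {
        "head": 0.14,
        "upper_trunk": 0.17,
        "middle_trunk": 0.12,
        "pelvis": 0.10,
        "upper_arm": 0.162,
        "forearm": 0.155,
        "hand": 0.06,
        "upper_leg": 0.245,
        "lower_leg": 0.25,
        "foot": 0.152,
    }
    return {k: v * height_m for k, v in fractions.items()}


@dataclass
class SyntheticTrialSpec:
    """Conditions of one generated walking trial (defaults: normal-speed gait
    of the study population average subject at 240 Hz)."""

    n_strides: int = 6
    stride_duration: float = 1.1  # s
    double_support_fraction: float = 0.12  # of stride, per double-support phase
    walking_speed: float = 1.28  # m/s
    fs: float = 240.0  # Hz
    total_mass: float = 77.34  # kg, measured (net body + instrumentation)
    height: float = 1.81  # m
    heading_deg: float = 0.0  # walking direction in the global frame
    vertical_amplitude: float = 0.15  # total Fz oscillation, fraction of BW
    anterior_amplitude: float = 0.15  # total Fx amplitude, fraction of BW
    lateral_amplitude: float = 0.04  # total Fy amplitude, fraction of BW
    leg_swing_amplitude: float = 0.06  # m, antisymmetric limb translation
    arm_swing_amplitude: float = 0.03  # m, counter-phase to the legs
    noise_acc_sd: float = 0.0  # m/s^2, white noise on linear accelerations
    noise_gyro_sd: float = 0.0  # rad/s, white noise on angular velocities
    seed: int = 0
    sta: STAFunction = field(default_factory=default_sta)

    def __post_init__(self) -> None:
        if not 0.0 < self.double_support_fraction < 0.5:
            raise NumericalError("double-support fraction must lie in (0, 0.5)")
        if self.stride_duration <= 0 or self.n_strides < 1:
            raise NumericalError("stride schedule must be positive")


@dataclass
class SyntheticTrial:
    """Generated kinematics plus every ground-truth quantity."""

    spec: SyntheticTrialSpec
    time: np.ndarray
    body: BodyModel
    kinematics: SegmentKinematicsSeries
    points: dict[str, PointTrajectory]
    frame: FramePair
    truth_total_w: WrenchSeries  # walking frame, moment about the global origin
    truth_left: WrenchSeries  # walking frame, about own ankle projection
    truth_right: WrenchSeries
    truth_events: GaitEventTable
    v_th: float


def _segment_layout(height: float, lengths: dict[str, float]):
    """Standing offsets (m) and constant orientations of the 16 segments."""
    h = height
    z_ut = 0.85 * h
    z_mt = z_ut - lengths["upper_trunk"]
    z_pelvis = z_mt - lengths["middle_trunk"]
    z_hip = 0.53 * h
    z_knee = z_hip - lengths["upper_leg"]
    z_ankle = z_knee - lengths["lower_leg"]
    z_shoulder = 0.82 * h
    z_elbow = z_shoulder - lengths["upper_arm"]
    z_wrist = z_elbow - lengths["forearm"]
    y_leg, y_arm = 0.09, 0.20

    offsets = {
        "head": np.array([0.0, 0.0, h]),
        "upper_trunk": np.array([0.0, 0.0, z_ut]),
        "middle_trunk": np.array([0.0, 0.0, z_mt]),
        "pelvis": np.array([0.0, 0.0, z_pelvis]),
    }
    quats = {name: QUAT_DOWN.copy() for name in offsets}
    for side, sign in (("l", 1.0), ("r", -1.0)):
        offsets[f"upper_arm_{side}"] = np.array([0.0, sign * y_arm, z_shoulder])
        offsets[f"forearm_{side}"] = np.array([0.0, sign * y_arm, z_elbow])
        offsets[f"hand_{side}"] = np.array([0.0, sign * y_arm, z_wrist])
        offsets[f"upper_leg_{side}"] = np.array([0.0, sign * y_leg, z_hip])
        offsets[f"lower_leg_{side}"] = np.array([0.0, sign * y_leg, z_knee])
        offsets[f"foot_{side}"] = np.array([-0.04, sign * y_leg, z_ankle])
        for seg in ("upper_arm", "forearm", "hand", "upper_leg", "lower_leg"):
            quats[f"{seg}_{side}"] = QUAT_DOWN.copy()
        quats[f"foot_{side}"] = QUAT_FORWARD.copy()
    return offsets, quats


def _pwl_eval(t: np.ndarray, bp: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Piecewise-linear profile evaluation (flat 0 outside the breakpoints)."""
    return np.interp(t, bp, vals, left=0.0, right=0.0)


def _pwl_integral(t: np.ndarray, bp: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Exact antiderivative of a piecewise-linear profile, zero before bp[0]."""
    seg_area = 0.5 * (vals[1:] + vals[:-1]) * np.diff(bp)
    cum = np.concatenate([[0.0], np.cumsum(seg_area)])
    idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, len(bp) - 2)
    t_in = np.clip(t, bp[0], bp[-1])
    dt_in = t_in - bp[idx]
    slope = (vals[idx + 1] - vals[idx]) / (bp[idx + 1] - bp[idx])
    out = cum[idx] + vals[idx] * dt_in + 0.5 * slope * dt_in**2
    out[t >= bp[-1]] = cum[-1]
    return out


class _Schedule:
    """Grid-aligned gait event schedule (times are exact sample multiples)."""

    def __init__(self, spec: SyntheticTrialSpec) -> None:
        fs = spec.fs
        self.dt = 1.0 / fs
        self.i_stride = 2 * max(1, round(spec.stride_duration * fs / 2.0))
        self.i_half = self.i_stride // 2
        self.i_ds = max(2, round(spec.double_support_fraction * self.i_stride))
        self.i_off = round(0.2 * fs)
        self.i_tail = round(0.25 * fs)
        self.T = self.i_stride * self.dt
        self.ds = self.i_ds * self.dt
        n_str = spec.n_strides
        self.n_samples = self.i_off + n_str * self.i_stride + self.i_tail + 1
        self.time = np.arange(self.n_samples) * self.dt
        self.duration = self.time[-1]
        k = np.arange(n_str + 1)
        # event times are integer sample counts times dt, so they compare
        # exactly equal to entries of the time grid
        hs_r = (self.i_off + k * self.i_stride) * self.dt
        to_l = (self.i_off + k * self.i_stride + self.i_ds) * self.dt
        hs_l = (self.i_off + k[:-1] * self.i_stride + self.i_half) * self.dt
        to_r = (self.i_off + k[:-1] * self.i_stride + self.i_half + self.i_ds) * self.dt
        horizon = self.duration - 2 * self.dt
        self.hs_r = hs_r[hs_r <= horizon]
        self.to_l = to_l[to_l <= horizon]
        self.hs_l = hs_l[hs_l <= horizon]
        self.to_r = to_r[to_r <= horizon]
        self.swing = self.T - self.i_half * self.dt - self.ds  # swing duration


def _foot_speed_profiles(sched: _Schedule, spec: SyntheticTrialSpec, side: str):
    """Trapezoidal heel and toe speed profiles with pinned threshold crossings."""
    v = spec.walking_speed
    vpk = 3.0 * v
    T = sched.T
    heel_fall = 0.18 * T
    k_heel = vpk / heel_fall
    toe_rise = 0.08 * T
    k_toe = vpk / toe_rise
    half_dt = 0.5 * sched.dt

    hs = sched.hs_l if side == "left" else sched.hs_r
    to = sched.to_l if side == "left" else sched.to_r
    # one virtual stride beyond the schedule keeps the heel fast through any
    # final swing, so the trial cannot end on a spurious below-threshold dip
    if len(hs):
        hs = np.append(hs, hs[-1] + sched.T)

    heel_bp: list[float] = []
    heel_v: list[float] = []
    for t_hs in hs:
        t_to = t_hs - sched.swing  # pseudo toe-off opening this swing
        a1 = t_to - 0.08 * T
        t_cross = t_hs - half_dt
        t_fall = t_cross - (vpk - 0.6 * v) / k_heel
        t_zero = t_cross + 0.6 * v / k_heel
        heel_bp += [a1, a1 + 0.06 * T, t_fall, t_zero]
        heel_v += [0.0, vpk, vpk, 0.0]
    toe_bp: list[float] = []
    toe_v: list[float] = []
    for t_to in to:
        t_hs_next = t_to + sched.swing
        t_cross = t_to - half_dt
        a1 = t_cross - 1.9 * v / k_toe
        toe_bp += [a1, a1 + toe_rise, t_hs_next - 0.1 * T, t_hs_next]
        toe_v += [0.0, vpk, vpk, 0.0]
    return (np.asarray(heel_bp), np.asarray(heel_v)), (np.asarray(toe_bp), np.asarray(toe_v))


def _ankle_trajectory(sched: _Schedule, spec: SyntheticTrialSpec, side: str):
    """Ankle path: stationary in stance, raised-cosine advance in swing."""
    v, T = spec.walking_speed, sched.T
    stride_len = v * T
    t = sched.time
    hs = sched.hs_l if side == "left" else sched.hs_r
    to = sched.to_l if side == "left" else sched.to_r
    sign = 1.0 if side == "left" else -1.0
    z_ankle = 0.035 * spec.height

    x = np.empty_like(t)
    vx = np.zeros_like(t)
    # stance position associated with the heel strike at t_hs
    landing = {float(t_hs): v * t_hs + 0.25 * stride_len for t_hs in hs}
    first_hs = hs[0] if len(hs) else np.inf
    x[:] = np.nan
    # before the first heel strike: either initial stance (no prior TO) or swing
    for i, ti in enumerate(t):
        prior_hs = hs[hs <= ti]
        prior_to = to[to <= ti]
        if len(prior_hs) == 0 and len(prior_to) == 0:
            x[i] = v * first_hs + 0.25 * stride_len - stride_len  # standing one stride back
            continue
        if len(prior_to) == 0 or (len(prior_hs) and prior_hs[-1] >= prior_to[-1]):
            x[i] = landing[float(prior_hs[-1])]  # stance
            continue
        # swing from the last toe-off towards the next heel strike
        t_to = prior_to[-1]
        nxt = hs[hs > t_to]
        t_hs = nxt[0] if len(nxt) else t_to + sched.swing
        x0 = landing.get(float(t_hs), v * t_hs + 0.25 * stride_len) - stride_len
        u = np.clip((ti - t_to) / (t_hs - t_to), 0.0, 1.0)
        x[i] = x0 + stride_len * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        vx[i] = stride_len / (t_hs - t_to) * (1.0 - np.cos(2 * np.pi * u))
    pos = np.column_stack([x, np.full_like(t, sign * 0.09), np.full_like(t, z_ankle)])
    vel = np.column_stack([vx, np.zeros_like(t), np.zeros_like(t)])
    return pos, vel


def _heading_rotation(heading_deg: float) -> np.ndarray:
    a = np.deg2rad(heading_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_trial(spec: SyntheticTrialSpec) -> SyntheticTrial:
    """Generate one synthetic walking trial with full ground truth."""
    sched = _Schedule(spec)
    t = sched.time
    n = sched.n_samples
    g = 9.81
    g_vec = np.array([0.0, 0.0, -g])

    table = load_deleva_table()
    lengths = default_segment_lengths(spec.height)
    body = scale_body(
        table, spec.total_mass, spec.height, lengths, instrumentation=default_instrumentation()
    )
    mass = spec.total_mass
    bw = mass * g

    # -- analytic total force (track frame: x = walking direction) ----------
    w_step = 2.0 * np.pi * 2.0 / sched.T
    w_stride = 2.0 * np.pi / sched.T
    t0 = sched.i_off * sched.dt
    t_pk = t0 + 0.15 * sched.T / 2.0
    fz = bw * (1.0 + spec.vertical_amplitude * np.cos(w_step * (t - t_pk)))
    fx = -bw * spec.anterior_amplitude * np.sin(w_step * (t - t0) - np.pi / 4.0)
    fy = bw * spec.lateral_amplitude * np.sin(w_stride * (t - t0) + np.pi / 3.0)
    if np.min(fz) <= 0.0:
        raise NumericalError("infeasible force profile: vertical force must stay positive")

    # CoM motion is the exact double integral of (F/m + g)
    az = g * spec.vertical_amplitude * np.cos(w_step * (t - t_pk))
    ax = -g * spec.anterior_amplitude * np.sin(w_step * (t - t0) - np.pi / 4.0)
    ay = g * spec.lateral_amplitude * np.sin(w_stride * (t - t0) + np.pi / 3.0)
    com_acc = np.column_stack([ax, ay, az])
    vx = spec.walking_speed + g * spec.anterior_amplitude / w_step * np.cos(w_step * (t - t0) - np.pi / 4.0)
    vy = -g * spec.lateral_amplitude / w_stride * np.cos(w_stride * (t - t0) + np.pi / 3.0)
    vz = g * spec.vertical_amplitude / w_step * np.sin(w_step * (t - t_pk))
    com_vel = np.column_stack([vx, vy, vz])
    cx = spec.walking_speed * t + g * spec.anterior_amplitude / w_step**2 * np.sin(w_step * (t - t0) - np.pi / 4.0)
    cy = -g * spec.lateral_amplitude / w_stride**2 * np.sin(w_stride * (t - t0) + np.pi / 3.0)
    cz = 0.57 * spec.height - g * spec.vertical_amplitude / w_step**2 * np.cos(w_step * (t - t_pk))
    com_pos = np.column_stack([cx, cy, cz])

    # -- antisymmetric limb swing ------------------------------------------
    phi = 0.31 * sched.T
    swing = np.sin(w_stride * (t - t0 - phi))
    swing_acc = -(w_stride**2) * np.sin(w_stride * (t - t0 - phi))
    pair_delta = {}  # left member's displacement along x; right gets the negative
    for seg in ("upper_leg", "lower_leg", "foot"):
        pair_delta[seg] = spec.leg_swing_amplitude
    for seg in ("upper_arm", "forearm", "hand"):
        pair_delta[seg] = -spec.arm_swing_amplitude  # arms counter-swing

    offsets, quats = _segment_layout(spec.height, lengths)
    from scipy.spatial.transform import Rotation as _R

    com_local_global = {}
    for name, seg in body.segments.items():
        rot = _R.from_quat(np.asarray(quats[name])[[1, 2, 3, 0]])
        com_local_global[name] = rot.apply(seg.com_offset_local)
    # base translation keeps the whole-body CoM on the prescribed path
    static_com = sum(
        body.segments[nm].mass * (offsets[nm] + com_local_global[nm]) for nm in body.segments
    ) / mass
    base = com_pos - static_com  # (n, 3)

    # swing cross-term folded into the ground-truth moment:
    #   sum_pairs m_pair (e_L - e_R) x ddelta_L,  delta parallel to x
    m_extra_z = np.zeros(n)
    for seg, amp in pair_delta.items():
        m_seg = body.segments[f"{seg}_l"].mass
        e_l = offsets[f"{seg}_l"] + com_local_global[f"{seg}_l"]
        e_r = offsets[f"{seg}_r"] + com_local_global[f"{seg}_r"]
        dy = e_l[1] - e_r[1]
        m_extra_z += -m_seg * dy * amp * swing_acc

    R_head = _heading_rotation(spec.heading_deg)
    rot_head = _R.from_matrix(R_head)

    segments: dict[str, SegmentKinematics] = {}
    rng = np.random.default_rng(spec.seed)
    for name in body.segments:
        delta = np.zeros((n, 3))
        dacc = np.zeros((n, 3))
        stem = name[:-2] if name.endswith(("_l", "_r")) else name
        if stem in pair_delta and name.endswith(("_l", "_r")):
            sgn = 1.0 if name.endswith("_l") else -1.0
            delta[:, 0] = sgn * pair_delta[stem] * swing
            dacc[:, 0] = sgn * pair_delta[stem] * swing_acc
        pos = (base + offsets[name] + delta) @ R_head.T
        acc = (com_acc + dacc) @ R_head.T
        quat = (rot_head * _R.from_quat(np.asarray(quats[name])[[1, 2, 3, 0]])).as_quat()
        quat_wxyz = np.tile(quat[[3, 0, 1, 2]], (n, 1))
        ang_vel = np.zeros((n, 3))
        if spec.noise_acc_sd > 0:
            acc = acc + rng.normal(0.0, spec.noise_acc_sd, acc.shape)
        if spec.noise_gyro_sd > 0:
            ang_vel = ang_vel + rng.normal(0.0, spec.noise_gyro_sd, ang_vel.shape)
        segments[name] = SegmentKinematics(
            position=pos, quat_wxyz=quat_wxyz, lin_acc=acc, ang_vel=ang_vel, ang_acc=None
        )
    kin = SegmentKinematicsSeries(time=t, segments=segments)

    # -- tracked points ------------------------------------------------------
    points: dict[str, PointTrajectory] = {}
    pelvis_pos = (base + offsets["pelvis"]) @ R_head.T
    points["pelvis"] = PointTrajectory(position=pelvis_pos, velocity=com_vel @ R_head.T)
    for side in ("left", "right"):
        (h_bp, h_v), (t_bp, t_v) = _foot_speed_profiles(sched, spec, side)
        heel_speed = _pwl_eval(t, h_bp, h_v)
        toe_speed = _pwl_eval(t, t_bp, t_v)
        heel_x = _pwl_integral(t, h_bp, h_v)
        toe_x = _pwl_integral(t, t_bp, t_v)
        sign = 1.0 if side == "left" else -1.0
        y = np.full(n, sign * 0.09)
        heel_pos = np.column_stack([heel_x, y, np.full(n, 0.02)]) @ R_head.T
        toe_pos = np.column_stack([toe_x + lengths["foot"], y, np.full(n, 0.01)]) @ R_head.T
        heel_vel = np.column_stack([heel_speed, np.zeros(n), np.zeros(n)]) @ R_head.T
        toe_vel = np.column_stack([toe_speed, np.zeros(n), np.zeros(n)]) @ R_head.T
        points[f"heel_{side}"] = PointTrajectory(heel_pos, heel_vel)
        points[f"toe_{side}"] = PointTrajectory(toe_pos, toe_vel)
        a_pos, a_vel = _ankle_trajectory(sched, spec, side)
        points[f"ankle_{side}"] = PointTrajectory(a_pos @ R_head.T, a_vel @ R_head.T)

    # -- ground truth --------------------------------------------------------
    frame = walking_frame(pelvis_pos)
    force_track = np.column_stack([fx, fy, fz])
    moment_track = np.cross(com_pos, force_track)  # about the global origin
    moment_track[:, 2] += m_extra_z
    force_w = frame.to_walking(force_track @ R_head.T)
    moment_w = frame.to_walking(moment_track @ R_head.T)
    total_w = WrenchSeries(t, force_w, moment_w, np.zeros(3), frame="w")

    events = GaitEventTable(
        left=FootEvents(sched.hs_l.copy(), sched.to_l.copy()),
        right=FootEvents(sched.hs_r.copy(), sched.to_r.copy()),
    )
    ankle_w = {
        side: frame.to_walking(points[f"ankle_{side}"].position) for side in ("left", "right")
    }
    truth_left, truth_right = _split_truth(total_w, sched, spec.sta, ankle_w)

    return SyntheticTrial(
        spec=spec,
        time=t,
        body=body,
        kinematics=kin,
        points=points,
        frame=frame,
        truth_total_w=total_w,
        truth_left=truth_left,
        truth_right=truth_right,
        truth_events=events,
        v_th=spec.walking_speed,
    )


def _split_truth(
    total_w: WrenchSeries,
    sched: _Schedule,
    sta: STAFunction,
    ankle_w: dict[str, np.ndarray],
) -> tuple[WrenchSeries, WrenchSeries]:
    """Independent per-foot split of the analytic total (mirrors the gait-phase
    table directly from the schedule, not via the event/distribution modules)."""
    t = total_w.time
    n = len(t)
    ap = {}
    for side in ("left", "right"):
        proj = ankle_w[side].copy()
        proj[:, 2] = 0.0
        ap[side] = proj

    def moment_about(P: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # total moment re-expressed about per-sample points P (ref is origin)
        return total_w.moment[idx] - np.cross(P[idx], total_w.force[idx])

    force = {s: np.zeros((n, 3)) for s in ("left", "right")}
    moment = {s: np.zeros((n, 3)) for s in ("left", "right")}

    # stance intervals per foot (schedule semantics: stance in [HS, TO))
    stance = {}
    for side, hs, to in (
        ("left", sched.hs_l, sched.to_l),
        ("right", sched.hs_r, sched.to_r),
    ):
        mask = np.zeros(n, dtype=bool)
        hs_all = np.concatenate([[-np.inf] if (len(to) and (len(hs) == 0 or to[0] < hs[0])) else [], hs])
        for t_hs in hs_all:
            later_to = to[to > t_hs]
            t_to = later_to[0] if len(later_to) else np.inf
            mask |= (t >= t_hs) & (t < t_to)
        stance[side] = mask

    both = stance["left"] & stance["right"]
    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        only = stance[side] & ~stance[other]
        idx = np.flatnonzero(only)
        force[side][idx] = total_w.force[idx]
        moment[side][idx] = moment_about(ap[side], idx)

    episodes = [
        (t_hs, t_to, "left") for t_hs, t_to in zip(sched.hs_r, sched.to_l) if t_to <= t[-1]
    ]
    episodes += [
        (t_hs, t_to, "right") for t_hs, t_to in zip(sched.hs_l, sched.to_r) if t_to <= t[-1]
    ]
    for start, end, trailing in episodes:
        leading = "right" if trailing == "left" else "left"
        idx = np.flatnonzero(both & (t >= start) & (t < end))
        if len(idx) == 0:
            continue
        i0 = int(round(start / sched.dt))
        tau = (t[idx] - start) / (end - start)
        factors = sta(tau)
        tap = ap[trailing]
        anchor_f = total_w.force[i0]
        anchor_m = total_w.moment[i0] - np.cross(tap[i0], total_w.force[i0])
        force[trailing][idx] = anchor_f * factors[0:3].T
        moment[trailing][idx] = anchor_m * factors[3:6].T
        force[leading][idx] = total_w.force[idx] - force[trailing][idx]
        lead_m_at_tap = moment_about(tap, idx) - moment[trailing][idx]
        moment[leading][idx] = lead_m_at_tap + np.cross(
            tap[idx] - ap[leading][idx], force[leading][idx]
        )

    left = WrenchSeries(t, force["left"], moment["left"], ap["left"], frame="w")
    right = WrenchSeries(t, force["right"], moment["right"], ap["right"], frame="w")
    return left, right


def generate_static_pose(
    total_mass: float = 77.34,
    height: float = 1.81,
    duration_s: float = 2.0,
    fs: float = 240.0,
    left_share: float = 0.5,
) -> SyntheticTrial:
    """Motionless upright trial: the ground truth is pure body weight, split
    between the feet by ``left_share`` at the ankle points."""
    spec = SyntheticTrialSpec(total_mass=total_mass, height=height, fs=fs)
    g = 9.81
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    table = load_deleva_table()
    lengths = default_segment_lengths(height)
    body = scale_body(table, total_mass, height, lengths, instrumentation=default_instrumentation())
    offsets, quats = _segment_layout(height, lengths)
    segments = {
        name: SegmentKinematics(
            position=np.tile(offsets[name], (n, 1)),
            quat_wxyz=np.tile(quats[name], (n, 1)),
            lin_acc=np.zeros((n, 3)),
            ang_vel=np.zeros((n, 3)),
            ang_acc=np.zeros((n, 3)),
        )
        for name in body.segments
    }
    kin = SegmentKinematicsSeries(time=t, segments=segments)
    points = {
        "pelvis": PointTrajectory(np.tile(offsets["pelvis"], (n, 1)), np.zeros((n, 3))),
    }
    for side, sign in (("left", 1.0), ("right", -1.0)):
        ankle = np.tile([0.0, sign * 0.09, 0.035 * height], (n, 1))
        points[f"ankle_{side}"] = PointTrajectory(ankle, np.zeros((n, 3)))
        points[f"heel_{side}"] = PointTrajectory(ankle.copy(), np.zeros((n, 3)))
        points[f"toe_{side}"] = PointTrajectory(ankle.copy(), np.zeros((n, 3)))
    fz_total = total_mass * g
    shares = {"left": left_share, "right": 1.0 - left_share}
    wrenches = {}
    for side in ("left", "right"):
        ap = points[f"ankle_{side}"].position.copy()
        ap[:, 2] = 0.0
        force = np.zeros((n, 3))
        force[:, 2] = shares[side] * fz_total
        # weight acts through the whole-body CoM above the midline
        from scipy.spatial.transform import Rotation as _R

        com_g = {}
        for nm, seg in body.segments.items():
            rot = _R.from_quat(np.asarray(quats[nm])[[1, 2, 3, 0]])
            com_g[nm] = offsets[nm] + rot.apply(seg.com_offset_local)
        com = sum(body.segments[nm].mass * com_g[nm] for nm in body.segments) / total_mass
        lever = np.array([com[0], com[1], 0.0]) - ap[0]
        moment = np.cross(lever, force[0])
        wrenches[side] = WrenchSeries(t, force, np.tile(moment, (n, 1)), ap, frame="w")
    total = WrenchSeries(
        t,
        wrenches["left"].force + wrenches["right"].force,
        np.zeros((n, 3)),
        np.zeros(3),
        frame="w",
    )
    events = GaitEventTable(
        left=FootEvents(np.array([]), np.array([])), right=FootEvents(np.array([]), np.array([]))
    )
    return SyntheticTrial(
        spec=spec,
        time=t,
        body=body,
        kinematics=kin,
        points=points,
        frame=FramePair(yaw=0.0),
        truth_total_w=total,
        truth_left=wrenches["left"],
        truth_right=wrenches["right"],
        truth_events=events,
        v_th=0.0,
    )


# ---------------------------------------------------------------------------
# Analytic pendulum chain (rotational-dynamics oracle construction)


@dataclass
class PendulumChain:
    """Planar chain of rods with prescribed sinusoidal joint angles.

    Joint angle ``phi_i(t) = mean_i + amp_i sin(2 pi freq_i t + phase_i)`` is
    the absolute inclination of rod ``i`` from straight down, in the x-z plane.
    Linear/angular momenta are available in closed form so external-wrench
    implementations can be checked against momentum derivatives.
    """

    masses: tuple[float, ...] = (7.0, 3.5, 1.0)
    lengths: tuple[float, ...] = (0.45, 0.45, 0.25)
    amplitudes: tuple[float, ...] = (0.5, 0.8, 0.6)
    frequencies: tuple[float, ...] = (0.9, 1.3, 1.7)  # Hz
    phases: tuple[float, ...] = (0.0, 1.0, 2.0)
    means: tuple[float, ...] = (0.2, -0.1, 0.3)
    com_fraction: float = 0.5
    gyration: tuple[float, float, float] = (0.3, 0.3, 0.05)
    base: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.5]))
    gravity: float = 9.81

    @property
    def n_links(self) -> int:
        return len(self.masses)

    def _phi(self, t: np.ndarray):
        t = np.atleast_1d(np.asarray(t, float))
        phi, dphi, ddphi = [], [], []
        for A, f, p, m in zip(self.amplitudes, self.frequencies, self.phases, self.means):
            w = 2.0 * np.pi * f
            phi.append(m + A * np.sin(w * t + p))
            dphi.append(A * w * np.cos(w * t + p))
            ddphi.append(-A * w**2 * np.sin(w * t + p))
        return phi, dphi, ddphi

    def _link_states(self, t: np.ndarray):
        """Per-link origin/CoM positions, velocities, accelerations (closed form)."""
        t = np.atleast_1d(np.asarray(t, float))
        phi, dphi, ddphi = self._phi(t)
        n = len(t)
        joint_p = np.tile(self.base, (n, 1))
        joint_v = np.zeros((n, 3))
        joint_a = np.zeros((n, 3))
        states = []
        for i in range(self.n_links):
            u = np.column_stack([np.sin(phi[i]), np.zeros(n), -np.cos(phi[i])])
            up = np.column_stack([np.cos(phi[i]), np.zeros(n), np.sin(phi[i])])
            du = dphi[i][:, None] * up
            ddu = ddphi[i][:, None] * up - (dphi[i] ** 2)[:, None] * u
            L, f = self.lengths[i], self.com_fraction
            states.append(
                {
                    "origin_p": joint_p.copy(),
                    "origin_v": joint_v.copy(),
                    "origin_a": joint_a.copy(),
                    "com_p": joint_p + f * L * u,
                    "com_v": joint_v + f * L * du,
                    "com_a": joint_a + f * L * ddu,
                    "phi": phi[i],
                    "dphi": dphi[i],
                    "ddphi": ddphi[i],
                    "u": u,
                }
            )
            joint_p = joint_p + L * u
            joint_v = joint_v + L * du
            joint_a = joint_a + L * ddu
        return states

    def body_model(self) -> BodyModel:
        segments = {}
        for i, (m, L) in enumerate(zip(self.masses, self.lengths)):
            segments[f"link{i}"] = ScaledSegment(
                name=f"link{i}",
                mass=m,
                length=L,
                com_offset_local=np.array([0.0, 0.0, self.com_fraction * L]),
                inertia_com_local=segment_inertia(m, L, self.gyration),
            )
        return BodyModel(
            segments=segments,
            total_mass=sum(self.masses),
            height=sum(self.lengths),
            gravity=np.array([0.0, 0.0, -self.gravity]),
        )

    def kinematics(self, t: np.ndarray) -> SegmentKinematicsSeries:
        """Sampled segment kinematics with exact analytic channels."""
        t = np.asarray(t, float)
        states = self._link_states(t)
        segments = {}
        for i, st in enumerate(states):
            # R = Ry(-phi) Rx(pi) maps the longitudinal axis onto u(phi)
            half = -0.5 * st["phi"]
            q_y = np.column_stack(
                [np.cos(half), np.zeros_like(half), np.sin(half), np.zeros_like(half)]
            )  # wxyz, rotation about y
            q_x = np.array([0.0, 1.0, 0.0, 0.0])
            quat = _quat_multiply(q_y, q_x)
            ang_vel = np.column_stack(
                [np.zeros_like(st["dphi"]), -st["dphi"], np.zeros_like(st["dphi"])]
            )
            ang_acc = np.column_stack(
                [np.zeros_like(st["ddphi"]), -st["ddphi"], np.zeros_like(st["ddphi"])]
            )
            segments[f"link{i}"] = SegmentKinematics(
                position=st["origin_p"],
                quat_wxyz=quat,
                lin_acc=st["origin_a"],
                ang_vel=ang_vel,
                ang_acc=ang_acc,
            )
        return SegmentKinematicsSeries(time=t, segments=segments)

    def linear_momentum(self, t: np.ndarray) -> np.ndarray:
        states = self._link_states(t)
        return sum(m * st["com_v"] for m, st in zip(self.masses, states))

    def angular_momentum(self, t: np.ndarray, ref_point: np.ndarray) -> np.ndarray:
        """About a fixed point: spin (J_yy omega) plus orbital terms."""
        states = self._link_states(t)
        ref = np.asarray(ref_point, float)
        total = np.zeros((len(np.atleast_1d(t)), 3))
        for m, L, st in zip(self.masses, self.lengths, states):
            J_yy = m * (self.gyration[1] * L) ** 2
            spin = np.column_stack(
                [np.zeros_like(st["dphi"]), -J_yy * st["dphi"], np.zeros_like(st["dphi"])]
            )
            total += spin + m * np.cross(st["com_p"] - ref, st["com_v"])
        return total


def _quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of wxyz quaternions (broadcasting over rows)."""
    q1 = np.atleast_2d(q1)
    q2 = np.atleast_2d(q2)
    w1, x1, y1, z1 = q1.T
    w2, x2, y2, z2 = q2.T
    return np.column_stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )
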