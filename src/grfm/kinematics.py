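"""Ingestion and conditioning of segment kinematics.

Input is a per-segment time series of origin position, orientation (unit
quaternion, segment frame to global), origin linear acceleration and angular
velocity, all expressed in the global frame and sampled on a uniform grid.
Angular accelerations may be supplied or obtained here by central finite
differences.  Channels entering the dynamics (a, omega, omega_dot) are
conditioned with a second-order zero-phase Butterworth low-pass filter
(forward-backward application, effective fourth-order magnitude, DC gain 1).

The walking frame differs from the global frame only by a yaw rotation; its
anterior axis points along the net horizontal displacement of the pelvis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, InputError

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 2


@dataclass
class SegmentKinematics:
    """Time series of one rigid segment, all vectors in the global frame."""

    position: np.ndarray  # (n, 3) origin position, m
    quat_wxyz: np.ndarray  # (n, 4) unit quaternion, segment -> global
    lin_acc: np.ndarray  # (n, 3) origin linear acceleration, m/s^2
    ang_vel: np.ndarray  # (n, 3) rad/s
    ang_acc: np.ndarray | None = None  # (n, 3) rad/s^2


@dataclass
class SegmentKinematicsSeries:
    time: np.ndarray  # (n,) s, uniform grid
    segments: dict[str, SegmentKinematics]

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def validate(self, quat_tol: float = 1e-6) -> None:
        dt = np.diff(self.time)
        if len(dt) == 0:
            raise InputError("kinematics series must contain at least two samples")
        if np.ptp(dt) > 1e-6 * np.mean(dt) + 1e-12:
            raise InputError("kinematics series must be uniformly sampled")
        for name, seg in self.segments.items():
            n = self.n_samples
            for attr in ("position", "quat_wxyz", "lin_acc", "ang_vel"):
                arr = getattr(seg, attr)
                if arr.shape[0] != n:
                    raise InputError(f"segment {name!r}: channel {attr} has wrong length")
            norms = np.linalg.norm(seg.quat_wxyz, axis=1)
            if np.max(np.abs(norms - 1.0)) > quat_tol:
                raise InputError(f"segment {name!r}: orientations are not unit quaternions")


@dataclass(frozen=True)
class PointTrajectory:
    """A tracked body point (heel, toe, pelvis origin, ankle joint)."""

    position: np.ndarray  # (n, 3) m, global frame
    velocity: np.ndarray | None = None  # (n, 3) m/s

    def speed(self) -> np.ndarray:
        if self.velocity is None:
            raise InputError("point trajectory carries no velocity; differentiate first")
        return np.linalg.norm(self.velocity, axis=1)


def filter_channel(x: np.ndarray, cutoff_hz: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass of one channel (or (n, k) array of them)."""
    if cutoff_hz >= fs / 2.0:
        raise ConfigurationError(
            f"cut-off {cutoff_hz} Hz must be below the Nyquist frequency {fs / 2.0} Hz"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= 3 * padlen:
        raise InputError("series too short for zero-phase filtering")
    return filtfilt(b, a, x, axis=0)


def lowpass_filter(
    series: SegmentKinematicsSeries,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> SegmentKinematicsSeries:
    """Filter the dynamic channels (lin_acc, ang_vel, ang_acc) of every segment.

    Positions and orientations are left untouched; they enter the dynamics only
    through lever arms, which the reference pipeline does not filter.
    """
    fs = series.fs
    out: dict[str, SegmentKinematics] = {}
    for name, seg in series.segments.items():
        out[name] = replace(
            seg,
            lin_acc=filter_channel(seg.lin_acc, cutoff_hz, fs, order),
            ang_vel=filter_channel(seg.ang_vel, cutoff_hz, fs, order),
            ang_acc=None
            if seg.ang_acc is None
            else filter_channel(seg.ang_acc, cutoff_hz, fs, order),
        )
    return SegmentKinematicsSeries(time=series.time, segments=out)


def differentiate(x: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Central finite differences on the uniform grid; one-sided at the ends."""
    if x.shape[0] < 3:
        raise InputError("need at least 3 samples to differentiate")
    return np.gradient(x, time, axis=0)


def differentiate_angular_velocity(series: SegmentKinematicsSeries) -> SegmentKinematicsSeries:
    """Fill ``ang_acc`` for every segment by differentiating ``ang_vel``."""
    out = {
        name: replace(seg, ang_acc=differentiate(seg.ang_vel, series.time))
        for name, seg in series.segments.items()
    }
    return SegmentKinematicsSeries(time=series.time, segments=out)


def translate_acceleration_to_com(
    a_origin: np.ndarray,
    ang_vel: np.ndarray,
    ang_acc: np.ndarray,
    r_origin_to_com: np.ndarray,
) -> np.ndarray:
    """Rigid-body acceleration transfer ``a_com = a_o + dw x r + w x (w x r)``.

    All arguments are (n, 3) arrays (or broadcastable) in one common frame;
    ``r_origin_to_com`` is the origin-to-CoM vector expressed in that frame.
    """
    r = np.broadcast_to(r_origin_to_com, a_origin.shape)
    return a_origin + np.cross(ang_acc, r) + np.cross(ang_vel, np.cross(ang_vel, r))


@dataclass(frozen=True)
class FramePair:
    """Yaw rotation from the global frame to the walking frame.

    The rotation leaves the vertical axis fixed; ``yaw`` is the heading of the
    walking direction in the global frame (radians about +z).
    """

    yaw: float

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.yaw), np.sin(self.yaw)
        # v_w = Rz(-yaw) v_g
        return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    def to_walking(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation_matrix().T

    def from_walking(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation_matrix()


def walking_frame(pelvis_positions: np.ndarray, min_displacement: float = 0.5) -> FramePair:
    """Derive the walking frame from initial and final pelvis positions.

    Assumes an approximately straight walk; raises ``InputError`` when the
    horizontal pelvis displacement is below ``min_displacement`` metres, in
    which case the walking direction is undefined.
    """
    disp = np.asarray(pelvis_positions[-1]) - np.asarray(pelvis_positions[0])
    horizontal = np.hypot(disp[0], disp[1])
    if horizontal < min_displacement:
        raise InputError(
            f"walking direction undefined: horizontal pelvis displacement "
            f"{horizontal:.3f} m is below {min_displacement} m"
        )
    return FramePair(yaw=float(np.arctan2(disp[1], disp[0])))


# ---------------------------------------------------------------------------
# CSV / JSON schema

_SEG_COLS = ("px", "py", "pz", "qw", "qx", "qy", "qz", "ax", "ay", "az", "wx", "wy", "wz")
_ANGACC_COLS = ("dwx", "dwy", "dwz")
_POINT_COLS = ("px", "py", "pz")
_POINT_VEL_COLS = ("vx", "vy", "vz")


def write_kinematics_csv(
    series: SegmentKinematicsSeries,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
    points: dict[str, PointTrajectory] | None = None,
) -> None:
    """Write the kinematics (and optional tracked points) with a JSON sidecar."""
    csv_path = Path(csv_path)
    cols: dict[str, np.ndarray] = {"time": series.time}
    for name, seg in series.segments.items():
        block = [seg.position, seg.quat_wxyz, seg.lin_acc, seg.ang_vel]
        labels = list(_SEG_COLS)
        if seg.ang_acc is not None:
            block.append(seg.ang_acc)
            labels += list(_ANGACC_COLS)
        data = np.hstack(block)
        for j, lab in enumerate(labels):
            cols[f"{name}_{lab}"] = data[:, j]
    for pname, point in (points or {}).items():
        for j, lab in enumerate(_POINT_COLS):
            cols[f"point_{pname}_{lab}"] = point.position[:, j]
        if point.velocity is not None:
            for j, lab in enumerate(_POINT_VEL_COLS):
                cols[f"point_{pname}_{lab}"] = point.velocity[:, j]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "fs_hz": series.fs,
        "segments": list(series.segments),
        "points": list(points or {}),
        "units": "SI",
        "frame": "global",
    }
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def read_kinematics_csv(
    csv_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[SegmentKinematicsSeries, dict[str, PointTrajectory]]:
    """Read kinematics written by :func:`write_kinematics_csv`."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except FileNotFoundError as exc:
        raise InputError(f"missing kinematics sidecar {sidecar_path}") from exc
    df = pd.read_csv(csv_path)
    if "time" not in df.columns:
        raise InputError("kinematics CSV lacks a 'time' column")
    time = df["time"].to_numpy(dtype=float)

    def grab(prefix: str, labels: tuple[str, ...], required: bool) -> np.ndarray | None:
        names = [f"{prefix}_{lab}" for lab in labels]
        missing = [c for c in names if c not in df.columns]
        if missing:
            if required:
                raise InputError(f"kinematics CSV lacks columns {missing}")
            return None
        return df[names].to_numpy(dtype=float)

    segments: dict[str, SegmentKinematics] = {}
    for name in sidecar["segments"]:
        pos = grab(name, _SEG_COLS[0:3], True)
        quat = grab(name, _SEG_COLS[3:7], True)
        acc = grab(name, _SEG_COLS[7:10], True)
        angvel = grab(name, _SEG_COLS[10:13], True)
        angacc = grab(name, _ANGACC_COLS, False)
        segments[name] = SegmentKinematics(pos, quat, acc, angvel, angacc)
    points: dict[str, PointTrajectory] = {}
    for pname in sidecar.get("points", []):
        pos = grab(f"point_{pname}", _POINT_COLS, True)
        vel = grab(f"point_{pname}", _POINT_VEL_COLS, False)
        points[pname] = PointTrajectory(position=pos, velocity=vel)
    series = SegmentKinematicsSeries(time=time, segments=segments)
    series.validate()
    return series, points
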