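"""Total external wrench from Newton-Euler equations of motion.

With the ground contact assumed to be the only significant external load, the
total external force is ``F_ext = sum_i m_i (a_i - g)`` over segment CoM
accelerations, and the total external moment about a reference point ``O`` is

    M_ext(O) = sum_i [ R_i J_i R_i^T dw_i + w_i x (R_i J_i R_i^T w_i)
                       + (c_i - O) x m_i (a_i - g) ]

where internal joint forces cancel pairwise over the closed chain.  Inertia
tensors are stored in segment frames and rotated per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .body import BodyModel
from .errors import InputError
from .kinematics import FramePair, SegmentKinematicsSeries, translate_acceleration_to_com

WRENCH_COLUMNS = ("fx", "fy", "fz", "mx", "my", "mz", "ref_x", "ref_y", "ref_z")


@dataclass
class WrenchSeries:
    """Force/moment time series with an explicit moment reference point."""

    time: np.ndarray  # (n,) s
    force: np.ndarray  # (n, 3) N
    moment: np.ndarray  # (n, 3) N m
    ref_point: np.ndarray  # (n, 3) m, point the moment is expressed about
    frame: str = "g"  # "g" (global) or "w" (walking)

    def __post_init__(self) -> None:
        n = len(self.time)
        self.force = np.asarray(self.force, dtype=float).reshape(n, 3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(n, 3)
        ref = np.asarray(self.ref_point, dtype=float)
        if ref.ndim == 1:
            ref = np.broadcast_to(ref, (n, 3)).copy()
        self.ref_point = ref.reshape(n, 3)

    def copy(self) -> "WrenchSeries":
        return WrenchSeries(
            self.time.copy(), self.force.copy(), self.moment.copy(),
            self.ref_point.copy(), self.frame,
        )


def _quat_to_rotation(quat_wxyz: np.ndarray) -> Rotation:
    return Rotation.from_quat(quat_wxyz[:, [1, 2, 3, 0]])  # scipy wants xyzw


def com_kinematics(
    body: BodyModel, kin: SegmentKinematicsSeries
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-segment CoM positions and accelerations in the global frame.

    The stored origin acceleration is transferred to the CoM with the segment's
    angular velocity and acceleration; requires ``ang_acc`` to be present.
    """
    _check_segments(body, kin)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, seg in kin.segments.items():
        if seg.ang_acc is None:
            raise InputError(
                f"segment {name!r} has no angular acceleration; call "
                "differentiate_angular_velocity first"
            )
        rot = _quat_to_rotation(seg.quat_wxyz)
        r_global = rot.apply(body.segments[name].com_offset_local)
        com_pos = seg.position + r_global
        com_acc = translate_acceleration_to_com(seg.lin_acc, seg.ang_vel, seg.ang_acc, r_global)
        out[name] = (com_pos, com_acc)
    return out


def _check_segments(body: BodyModel, kin: SegmentKinematicsSeries) -> None:
    if set(kin.segments) != set(body.segments):
        missing = set(body.segments) - set(kin.segments)
        extra = set(kin.segments) - set(body.segments)
        raise InputError(
            f"kinematics/body segment mismatch (missing {sorted(missing)}, extra {sorted(extra)})"
        )


def total_external_force(body: BodyModel, kin: SegmentKinematicsSeries) -> WrenchSeries:
    """Newton's equation summed over segments: ``F_ext = sum m_i (a_i - g)``."""
    coms = com_kinematics(body, kin)
    n = kin.n_samples
    force = np.zeros((n, 3))
    for name, (_, acc) in coms.items():
        force += body.segments[name].mass * (acc - body.gravity)
    return WrenchSeries(kin.time, force, np.zeros((n, 3)), np.zeros(3), frame="g")


def total_external_moment(
    body: BodyModel, kin: SegmentKinematicsSeries, ref_point: np.ndarray
) -> WrenchSeries:
    """Euler's equation about ``ref_point`` (a fixed (3,) point or (n, 3) series).

    Returns the full external wrench (force and moment).
    """
    coms = com_kinematics(body, kin)
    n = kin.n_samples
    ref = np.asarray(ref_point, dtype=float)
    if ref.ndim == 1:
        ref = np.broadcast_to(ref, (n, 3))
    force = np.zeros((n, 3))
    moment = np.zeros((n, 3))
    for name, (pos, acc) in coms.items():
        seg = kin.segments[name]
        model = body.segments[name]
        R = _quat_to_rotation(seg.quat_wxyz).as_matrix()  # (n, 3, 3)
        J_world = np.einsum("nij,jk,nlk->nil", R, model.inertia_com_local, R)
        gyro = np.einsum("nij,nj->ni", J_world, seg.ang_acc) + np.cross(
            seg.ang_vel, np.einsum("nij,nj->ni", J_world, seg.ang_vel)
        )
        f_i = model.mass * (acc - body.gravity)
        force += f_i
        moment += gyro + np.cross(pos - ref, f_i)
    return WrenchSeries(kin.time, force, moment, ref.copy(), frame="g")


def transfer_wrench(wrench: WrenchSeries, new_ref_point: np.ndarray) -> WrenchSeries:
    """Re-express the moment about a new reference point; the force is unchanged.

    ``M' = M + (old_ref - new_ref) x F``; involutive up to round-off.
    """
    n = len(wrench.time)
    new_ref = np.asarray(new_ref_point, dtype=float)
    if new_ref.ndim == 1:
        new_ref = np.broadcast_to(new_ref, (n, 3))
    moment = wrench.moment + np.cross(wrench.ref_point - new_ref, wrench.force)
    return WrenchSeries(wrench.time, wrench.force.copy(), moment, new_ref.copy(), wrench.frame)


def rotate_wrench(wrench: WrenchSeries, frame: FramePair) -> WrenchSeries:
    """Rotate a global-frame wrench into the walking frame (yaw about vertical)."""
    if wrench.frame != "g":
        raise InputError("rotate_wrench expects a global-frame wrench")
    return WrenchSeries(
        wrench.time,
        frame.to_walking(wrench.force),
        frame.to_walking(wrench.moment),
        frame.to_walking(wrench.ref_point),
        frame="w",
    )


def write_wrench_csv(wrench: WrenchSeries, path: str | Path) -> None:
    data = np.hstack([wrench.time[:, None], wrench.force, wrench.moment, wrench.ref_point])
    pd.DataFrame(data, columns=("time",) + WRENCH_COLUMNS).to_csv(Path(path), index=False)


def read_wrench_csv(path: str | Path, frame: str = "w") -> WrenchSeries:
    df = pd.read_csv(Path(path))
    missing = [c for c in ("time",) + WRENCH_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"wrench CSV lacks columns {missing}")
    return WrenchSeries(
        time=df["time"].to_numpy(float),
        force=df[["fx", "fy", "fz"]].to_numpy(float),
        moment=df[["mx", "my", "mz"]].to_numpy(float),
        ref_point=df[["ref_x", "ref_y", "ref_z"]].to_numpy(float),
        frame=frame,
    )
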