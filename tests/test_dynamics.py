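"""Newton-Euler totals, wrench transfer, and the momentum-derivative oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grfm.body import BodyModel, ScaledSegment, segment_inertia
from grfm.dynamics import (
    WrenchSeries,
    rotate_wrench,
    total_external_force,
    total_external_moment,
    transfer_wrench,
)
from grfm.errors import InputError
from grfm.kinematics import FramePair, SegmentKinematics, SegmentKinematicsSeries


def _single_segment_body(mass=2.0, length=0.4):
    seg = ScaledSegment(
        name="rod",
        mass=mass,
        length=length,
        com_offset_local=np.zeros(3),
        inertia_com_local=segment_inertia(mass, length, (0.3, 0.3, 0.1)),
    )
    return BodyModel(segments={"rod": seg}, total_mass=mass, height=length)


def _single_segment_kin(n=10, ang_vel=(0, 0, 0), ang_acc=(0, 0, 0), lin_acc=(0, 0, 0)):
    t = np.arange(n) / 240.0
    return SegmentKinematicsSeries(
        time=t,
        segments={
            "rod": SegmentKinematics(
                position=np.zeros((n, 3)),
                quat_wxyz=np.tile([1.0, 0, 0, 0], (n, 1)),
                lin_acc=np.tile(lin_acc, (n, 1)).astype(float),
                ang_vel=np.tile(ang_vel, (n, 1)).astype(float),
                ang_acc=np.tile(ang_acc, (n, 1)).astype(float),
            )
        },
    )


def test_static_pose_supports_body_weight(static_trial):
    f = total_external_force(static_trial.body, static_trial.kinematics)
    assert np.allclose(f.force[:, :2], 0.0, atol=1e-9)
    assert np.allclose(f.force[:, 2], 77.34 * 9.81, atol=1e-9)


def test_free_fall_cancels_gravity():
    body = _single_segment_body()
    kin = _single_segment_kin(lin_acc=(0.0, 0.0, -9.81))
    f = total_external_force(body, kin)
    assert np.allclose(f.force, 0.0, atol=1e-12)


def test_segment_count_mismatch_is_rejected(static_trial):
    body = _single_segment_body()
    with pytest.raises(InputError, match="mismatch"):
        total_external_force(body, static_trial.kinematics)


def test_torque_free_steady_spin_about_principal_axis():
    body = _single_segment_body()
    kin = _single_segment_kin(ang_vel=(0, 0, 5.0), lin_acc=(0, 0, -9.81))
    w = total_external_moment(body, kin, np.zeros(3))
    assert np.allclose(w.moment, 0.0, atol=1e-12)


def test_angular_acceleration_about_principal_axis_gives_j_alpha():
    body = _single_segment_body(mass=2.0, length=0.4)
    alpha = 3.0
    kin = _single_segment_kin(ang_acc=(0, 0, alpha), lin_acc=(0, 0, -9.81))
    w = total_external_moment(body, kin, np.zeros(3))
    j_zz = 2.0 * (0.1 * 0.4) ** 2
    assert np.allclose(w.moment[:, 2], j_zz * alpha, atol=1e-12)
    assert np.allclose(w.moment[:, :2], 0.0, atol=1e-12)


def test_static_moment_vanishes_below_centre_of_mass(static_trial):
    from grfm.dynamics import com_kinematics

    coms = com_kinematics(static_trial.body, static_trial.kinematics)
    com = sum(
        static_trial.body.segments[nm].mass * pos[0]
        for nm, (pos, _) in coms.items()
    ) / static_trial.body.total_mass
    below = np.array([com[0], com[1], 0.0])
    w = total_external_moment(static_trial.body, static_trial.kinematics, below)
    assert np.allclose(w.moment[:, :2], 0.0, atol=1e-9)


class TestTransferWrench:
    def _wrench(self):
        rng = np.random.default_rng(7)
        t = np.arange(5) / 100.0
        return WrenchSeries(
            t,
            rng.normal(size=(5, 3)),
            rng.normal(size=(5, 3)),
            rng.normal(size=(5, 3)),
            frame="w",
        )

    def test_identity_and_definition(self):
        w = self._wrench()
        same = transfer_wrench(w, w.ref_point)
        assert np.allclose(same.moment, w.moment)
        d = np.array([0.1, -0.2, 0.3])
        moved = transfer_wrench(w, w.ref_point + d)
        assert np.allclose(moved.moment, w.moment + np.cross(-d, w.force))
        assert np.allclose(moved.force, w.force)

    def test_round_trip_recovers_input(self):
        w = self._wrench()
        back = transfer_wrench(transfer_wrench(w, np.array([1.0, 2.0, 3.0])), w.ref_point)
        assert np.max(np.abs(back.moment - w.moment)) < 1e-12

    def test_wrench_screw_is_preserved(self):
        w = self._wrench()
        moved = transfer_wrench(w, np.array([0.4, 0.5, -0.6]))
        f = w.force / np.linalg.norm(w.force, axis=1, keepdims=True)
        assert np.allclose(np.sum(w.moment * f, axis=1), np.sum(moved.moment * f, axis=1))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(yaw=st.floats(-np.pi, np.pi))
def test_frame_covariance_under_yaw(yaw, pendulum):
    """Rotating all inputs by a fixed yaw rotates the total wrench the same way."""
    chain, t, kin, body = pendulum
    frame = FramePair(yaw=yaw)
    R = frame.rotation_matrix().T  # global rotation by +yaw
    rotated = {}
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_matrix(R)
    for name, seg in kin.segments.items():
        q = Rotation.from_quat(seg.quat_wxyz[:, [1, 2, 3, 0]])
        q_new = (rot * q).as_quat()
        rotated[name] = SegmentKinematics(
            position=seg.position @ R.T,
            quat_wxyz=q_new[:, [3, 0, 1, 2]],
            lin_acc=seg.lin_acc @ R.T,
            ang_vel=seg.ang_vel @ R.T,
            ang_acc=seg.ang_acc @ R.T,
        )
    kin_rot = SegmentKinematicsSeries(time=t, segments=rotated)
    w = total_external_moment(body, kin, np.zeros(3))
    w_rot = total_external_moment(body, kin_rot, np.zeros(3))
    assert np.allclose(w_rot.force, w.force @ R.T, atol=1e-8)
    assert np.allclose(w_rot.moment, w.moment @ R.T, atol=1e-8)


def test_pendulum_chain_matches_momentum_derivative_oracle(pendulum):
    """Newton-Euler totals vs numerically differentiated analytic momenta."""
    chain, t, kin, body = pendulum
    ref = np.array([0.2, 0.0, 0.0])
    w = total_external_moment(body, kin, ref)
    h = 1e-4
    g_vec = np.array([0.0, 0.0, -chain.gravity])
    mass = sum(chain.masses)

    def d5(f):
        return (-f(t + 2 * h) + 8 * f(t + h) - 8 * f(t - h) + f(t - 2 * h)) / (12 * h)

    force_oracle = d5(chain.linear_momentum) - mass * g_vec
    l_dot = d5(lambda tt: chain.angular_momentum(tt, ref))
    gravity_moment = np.zeros_like(l_dot)
    for m, st_ in zip(chain.masses, chain._link_states(t)):
        gravity_moment += np.cross(st_["com_p"] - ref, m * g_vec)
    moment_oracle = l_dot - gravity_moment

    rel_f = np.max(np.linalg.norm(w.force - force_oracle, axis=1)) / np.max(
        np.linalg.norm(force_oracle, axis=1)
    )
    rel_m = np.max(np.linalg.norm(w.moment - moment_oracle, axis=1)) / np.max(
        np.linalg.norm(moment_oracle, axis=1)
    )
    assert rel_f < 1e-8
    assert rel_m < 1e-8


def test_rotate_wrench_requires_global_frame(trial):
    with pytest.raises(InputError):
        rotate_wrench(trial.truth_total_w, FramePair(0.0))
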