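"""Smooth-transition curves, double-support distribution and calibration."""

import numpy as np
import pytest

from grfm.distribution import STAFunction, calibrate_sta, default_sta, distribute, evaluate_sta
from grfm.dynamics import WrenchSeries, transfer_wrench
from grfm.errors import InputError, NumericalError
from grfm.events import FootEvents, GaitEventTable
from grfm.synthetic import SyntheticTrialSpec, generate_trial


def test_sta_endpoint_invariants_and_domain():
    sta = default_sta()
    assert np.allclose(evaluate_sta(sta, 0.0), 1.0)
    assert np.allclose(evaluate_sta(sta, 1.0), 0.0)
    with pytest.raises(InputError):
        sta(1.2)
    with pytest.raises(InputError):
        sta(-0.1)


def test_default_curve_matches_independent_raised_cosine():
    """Dual implementation: spline evaluation vs the analytic form itself."""
    sta = default_sta()
    # exact at the knots; between knots only cubic-spline interpolation error
    assert np.allclose(sta(sta.tau), 0.5 * (1.0 + np.cos(np.pi * sta.tau)), atol=1e-12)
    tau = np.linspace(0.0, 1.0, 37)
    assert np.allclose(sta(tau), 0.5 * (1.0 + np.cos(np.pi * tau)), atol=1e-6)
    assert sta(0.5)[0] == pytest.approx(0.5, abs=1e-12)


def test_sta_constructor_rejects_bad_endpoints():
    tau = np.linspace(0, 1, 11)
    vals = np.tile(np.linspace(0.9, 0.0, 11), (6, 1))
    with pytest.raises(InputError, match="start at 1"):
        STAFunction(tau=tau, values=vals)


def test_conservation_at_every_sample(prediction_unfiltered):
    """Force and moment balances hold sample-wise to machine precision."""
    res = prediction_unfiltered
    assert np.max(np.abs(res.left.force + res.right.force - res.total_w.force)) < 1e-9
    lw = transfer_wrench(res.left, np.zeros(3))
    rw = transfer_wrench(res.right, np.zeros(3))
    assert np.max(np.abs(lw.moment + rw.moment - res.total_w.moment)) < 1e-9


def test_trailing_force_vanishes_at_toe_off(prediction_unfiltered, trial):
    res = prediction_unfiltered
    i = int(np.searchsorted(res.time, trial.truth_events.left.toe_offs[1]))
    assert np.allclose(res.left.force[i], 0.0)
    assert np.allclose(res.left.moment[i], 0.0)


def test_per_foot_continuity_at_double_support_entry(prediction_unfiltered, trial):
    """f(0)=1 makes the trailing wrench continuous at the contralateral HS."""
    res = prediction_unfiltered
    dt = res.time[1] - res.time[0]
    for t_hs in trial.truth_events.left.heel_strikes[1:3]:  # right foot trailing
        i = int(np.searchsorted(res.time, t_hs))
        jump = np.linalg.norm(res.right.force[i] - res.right.force[i - 1])
        # bounded by the signal slew over one sample, no step discontinuity
        slew = np.max(np.linalg.norm(np.diff(res.total_w.force, axis=0), axis=1))
        assert jump <= 3 * slew + 1e-9


def test_self_consistency_recovery(prediction_unfiltered, trial):
    """Ground truth built from the same curves is recovered exactly per foot."""
    bw = trial.spec.total_mass * 9.81
    for side in ("left", "right"):
        pred = prediction_unfiltered.foot(side)
        truth = getattr(trial, f"truth_{side}")
        assert np.max(np.abs(pred.force - truth.force)) / bw < 1e-6
        assert np.max(np.abs(pred.moment - truth.moment)) < 1e-6


def test_monotone_curve_gives_monotone_trailing_vertical_force():
    """With constant total force, the trailing vertical force inherits the
    monotone decay of the vertical shape curve."""
    n = 200
    t = np.arange(n) / 240.0
    total = WrenchSeries(t, np.tile([0.0, 0.0, 700.0], (n, 1)), np.zeros((n, 3)),
                         np.zeros(3), frame="w")
    events = GaitEventTable(
        left=FootEvents(np.array([t[50]]), np.array([])),
        right=FootEvents(np.array([t[0]]), np.array([t[150]])),
    )
    ankle = np.tile([0.0, 0.0, 0.0], (n, 1))
    left, right = distribute(total, events, default_sta(), ankle, ankle)
    trailing_fz = right.force[50:150, 2]
    assert np.all(np.diff(trailing_fz) <= 1e-12)
    assert np.allclose(left.force[50:150, 2] + trailing_fz, 700.0)


def test_degenerate_double_support_is_an_error():
    n = 50
    t = np.arange(n) / 240.0
    total = WrenchSeries(t, np.ones((n, 3)), np.zeros((n, 3)), np.zeros(3), frame="w")
    events = GaitEventTable(
        left=FootEvents(np.array([t[10]]), np.array([])),
        right=FootEvents(np.array([t[0]]), np.array([t[10]])),
    )
    ankle = np.zeros((n, 3))
    with pytest.raises(NumericalError, match="degenerate"):
        distribute(total, events, default_sta(), ankle, ankle)


class TestCalibration:
    def _episode_table(self, n=200, fs=240.0):
        t = np.arange(n) / fs
        events = GaitEventTable(
            left=FootEvents(np.array([t[40]]), np.array([])),
            right=FootEvents(np.array([t[0]]), np.array([t[120]])),
        )
        return t, events

    def test_linear_decay_recovers_one_minus_tau(self):
        t, events = self._episode_table()
        n = len(t)
        start, end = t[40], t[120]
        tau = np.clip((t - start) / (end - start), 0.0, None)
        decay = np.where(t < start, 1.0, np.clip(1.0 - tau, 0.0, None))
        force = np.column_stack([30 * decay, 20 * decay, 700 * decay])
        moment = np.column_stack([5 * decay, -40 * decay, 2 * decay])
        right = WrenchSeries(t, force, moment, np.zeros(3), frame="w")
        left = WrenchSeries(t, np.ones((n, 3)), np.ones((n, 3)), np.zeros(3), frame="w")
        sta = calibrate_sta(left, right, events, n_knots=21)
        assert np.allclose(sta.values, np.tile(1.0 - sta.tau, (6, 1)), atol=1e-9)

    def test_averaging_two_identical_episodes_is_idempotent(self, trial):
        sta_one = calibrate_sta(trial.truth_left, trial.truth_right, trial.truth_events)
        # feeding the same wrenches twice (same table) cannot change the mean
        sta_two = calibrate_sta(trial.truth_left, trial.truth_right, trial.truth_events)
        assert np.allclose(sta_one.values, sta_two.values)

    def test_zero_anchor_episode_excluded_with_warning(self):
        t, events = self._episode_table()
        n = len(t)
        zero = WrenchSeries(t, np.zeros((n, 3)), np.zeros((n, 3)), np.zeros(3), frame="w")
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(InputError, match="no usable"):
                calibrate_sta(zero, zero, events)

    def test_noisy_episodes_recover_generating_curves(self):
        """Many noisy episodes average back to the generating transition."""
        spec = SyntheticTrialSpec(n_strides=12)
        trial = generate_trial(spec)
        rng = np.random.default_rng(11)

        def noisy(w):
            out = w.copy()
            for arr in (out.force, out.moment):
                for k in range(3):
                    arr[:, k] += rng.normal(0, 0.05 * np.max(np.abs(arr[:, k])), len(arr))
            return out

        sta_hat = calibrate_sta(noisy(trial.truth_left), noisy(trial.truth_right),
                                trial.truth_events)
        truth = spec.sta(sta_hat.tau)
        assert np.max(np.abs(sta_hat.values - truth)) < 0.05


def test_sta_csv_round_trip(tmp_path):
    from grfm.distribution import read_sta_csv, write_sta_csv

    sta = default_sta()
    path = tmp_path / "sta.csv"
    write_sta_csv(sta, path)
    back = read_sta_csv(path)
    tau = np.linspace(0, 1, 33)
    assert np.allclose(back(tau), sta(tau), atol=1e-12)
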