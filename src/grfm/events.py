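"""Gait event detection and phase labelling.

Heel strikes and toe-offs are detected per foot by a two-state machine driven
by the speed of the heel and toe points.  The trial-specific threshold speed
``v_th`` is the norm of the average pelvis velocity; a heel strike is the first
sample in swing where the heel speed falls below ``0.6 v_th`` and a toe-off the
first sample in stance where the toe speed rises above ``1.9 v_th``.  A
force-plate reference detector applies a 5 N threshold on the vertical force.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

SIDES = ("left", "right")


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass
class ThresholdConfig:
    """Event-detection thresholds; multipliers apply to the pelvis speed."""

    v_th: float  # m/s
    heel_multiplier: float = 0.6
    toe_multiplier: float = 1.9
    min_gap_s: float = 0.05  # suppresses chatter near the threshold

    def __post_init__(self) -> None:
        if self.heel_multiplier <= 0 or self.toe_multiplier <= 0:
            raise InputError("threshold multipliers must be positive")


def compute_vth(pelvis_velocity: np.ndarray) -> float:
    """Norm of the time-averaged pelvis velocity vector (m/s)."""
    v = np.asarray(pelvis_velocity, dtype=float)
    if v.size == 0:
        raise InputError("empty pelvis velocity series")
    return float(np.linalg.norm(v.mean(axis=0)))


@dataclass
class FootEvents:
    heel_strikes: np.ndarray  # (k,) s, ascending
    toe_offs: np.ndarray  # (m,) s, ascending

    def merged(self) -> list[tuple[float, str]]:
        events = [(t, "HS") for t in self.heel_strikes] + [(t, "TO") for t in self.toe_offs]
        events.sort()
        for (t0, a), (t1, b) in zip(events, events[1:]):
            if a == b:
                raise InputError(f"foot events do not alternate near t={t0:g}-{t1:g} s")
        return events

    def initial_stance(self) -> bool:
        """Stance/swing state before the first recorded event."""
        events = self.merged()
        if not events:
            return True  # no events: standing
        return events[0][1] == "TO"  # a toe-off can only end a stance


@dataclass
class GaitEventTable:
    left: FootEvents
    right: FootEvents

    def foot(self, side: str) -> FootEvents:
        return self.left if side == "left" else self.right

    def stance_mask(self, side: str, time: np.ndarray) -> np.ndarray:
        """Boolean stance mask over the sample grid for one foot."""
        foot = self.foot(side)
        state = foot.initial_stance()
        mask = np.empty(len(time), dtype=bool)
        events = foot.merged()
        idx = 0
        for i, t in enumerate(time):
            while idx < len(events) and events[idx][0] <= t:
                state = events[idx][1] == "HS"
                idx += 1
            mask[i] = state
        return mask


def _detect_foot(
    time: np.ndarray, heel_speed: np.ndarray, toe_speed: np.ndarray, config: ThresholdConfig
) -> FootEvents:
    if config.v_th <= 0:
        raise InputError("v_th must be positive (pelvis velocities cancel to zero?)")
    hs_thr = config.heel_multiplier * config.v_th
    to_thr = config.toe_multiplier * config.v_th
    stance = bool(heel_speed[0] < hs_thr)  # initial state from the first heel sample
    heel_strikes: list[float] = []
    toe_offs: list[float] = []
    last_event = -np.inf
    for i, t in enumerate(time):
        if t - last_event < config.min_gap_s:
            continue
        if stance:
            if toe_speed[i] > to_thr:
                toe_offs.append(t)
                stance = False
                last_event = t
        else:
            if heel_speed[i] < hs_thr:
                heel_strikes.append(t)
                stance = True
                last_event = t
    return FootEvents(np.asarray(heel_strikes), np.asarray(toe_offs))


def detect_events(
    time: np.ndarray,
    heel_speeds: dict[str, np.ndarray],
    toe_speeds: dict[str, np.ndarray],
    config: ThresholdConfig,
) -> GaitEventTable:
    """Run the per-foot state machine on heel/toe speed norms for both feet."""
    feet = {}
    for side in SIDES:
        feet[side] = _detect_foot(time, heel_speeds[side], toe_speeds[side], config)
        if len(feet[side].heel_strikes) == 0 and len(feet[side].toe_offs) == 0:
            warnings.warn(f"no gait events detected for the {side} foot", stacklevel=2)
    return GaitEventTable(left=feet["left"], right=feet["right"])


def detect_events_forceplate(
    time: np.ndarray, vertical_forces: dict[str, np.ndarray], threshold_n: float = 5.0
) -> GaitEventTable:
    """Reference detector: HS at the upward and TO at the downward 5 N crossing."""
    feet = {}
    for side in SIDES:
        fz = np.asarray(vertical_forces[side], dtype=float)
        above = fz > threshold_n
        rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
        falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
        feet[side] = FootEvents(time[rises], time[falls])
    return GaitEventTable(left=feet["left"], right=feet["right"])


@dataclass(frozen=True)
class DoubleSupport:
    """One double-support episode: trailing foot about to toe off."""

    start: float  # contralateral (leading) heel strike
    end: float  # ipsilateral (trailing) toe-off
    trailing: str

    @property
    def leading(self) -> str:
        return other_side(self.trailing)


def double_support_episodes(events: GaitEventTable) -> list[DoubleSupport]:
    """Episodes bounded by a leading-foot heel strike and a trailing-foot toe-off."""
    episodes: list[DoubleSupport] = []
    for trailing in SIDES:
        leading = other_side(trailing)
        for t_to in events.foot(trailing).toe_offs:
            hs_lead = events.foot(leading).heel_strikes
            prior = hs_lead[hs_lead <= t_to]  # equality: zero-length overlap
            if len(prior) == 0:
                continue
            t_hs = float(prior[-1])
            # the leading HS must fall inside the trailing foot's stance
            own_hs = events.foot(trailing).heel_strikes
            own_prior = own_hs[own_hs < t_to]
            if len(own_prior) and own_prior[-1] > t_hs:
                continue  # leading HS predates the trailing stance: not an overlap
            episodes.append(DoubleSupport(start=t_hs, end=float(t_to), trailing=trailing))
    episodes.sort(key=lambda e: e.start)
    return episodes


#: Phase labels relative to a reference (ipsilateral) foot.
PHASE_DS1 = "DS1"
PHASE_SS_IPSI = "SS_ipsi"
PHASE_DS2 = "DS2"
PHASE_SS_CONTRA = "SS_contra"


def gait_cycles(events: GaitEventTable, foot: str = "right") -> list[tuple[float, float]]:
    """Cycles between consecutive heel strikes of the same foot."""
    hs = events.foot(foot).heel_strikes
    return [(float(a), float(b)) for a, b in zip(hs, hs[1:])]


def label_phases(
    events: GaitEventTable, time: np.ndarray, reference_foot: str = "right"
) -> np.ndarray:
    """Per-sample phase labels (DS1 / SS_ipsi / DS2 / SS_contra) per gait cycle.

    Samples outside any complete cycle of the reference foot are labelled ''.
    Raises ``InputError`` when the contralateral events do not fall in the
    expected order inside a cycle; cycles without any contralateral events are
    labelled as a single stance block (all-stance, no DS labels).
    """
    contra = other_side(reference_foot)
    labels = np.full(len(time), "", dtype=object)
    for t0, t1 in gait_cycles(events, reference_foot):
        sel = (time >= t0) & (time < t1)
        to_c = events.foot(contra).toe_offs
        hs_c = events.foot(contra).heel_strikes
        to_i = events.foot(reference_foot).toe_offs
        to_c_in = to_c[(to_c > t0) & (to_c < t1)]
        hs_c_in = hs_c[(hs_c > t0) & (hs_c < t1)]
        to_i_in = to_i[(to_i > t0) & (to_i < t1)]
        if len(to_c_in) == 0 and len(hs_c_in) == 0:
            labels[sel] = PHASE_SS_IPSI  # single all-stance block
            continue
        if len(to_c_in) < 1 or len(hs_c_in) < 1 or len(to_i_in) < 1:
            raise InputError(f"incomplete contralateral events in cycle {t0:g}-{t1:g} s")
        t_tol, t_hsl, t_tor = float(to_c_in[0]), float(hs_c_in[0]), float(to_i_in[0])
        if not (t0 < t_tol <= t_hsl <= t_tor < t1):
            raise InputError(f"inconsistent event ordering in cycle {t0:g}-{t1:g} s")
        labels[sel & (time < t_tol)] = PHASE_DS1
        labels[sel & (time >= t_tol) & (time < t_hsl)] = PHASE_SS_IPSI
        labels[sel & (time >= t_hsl) & (time < t_tor)] = PHASE_DS2
        labels[sel & (time >= t_tor)] = PHASE_SS_CONTRA
    return labels


def write_events_csv(events: GaitEventTable, time: np.ndarray, path) -> None:
    """Events CSV: foot, event_type, time_s, sample_index."""
    import pandas as pd

    rows = []
    for side in SIDES:
        foot = events.foot(side)
        for t, kind in foot.merged():
            rows.append(
                {
                    "foot": side,
                    "event_type": "heel_strike" if kind == "HS" else "toe_off",
                    "time_s": t,
                    "sample_index": int(np.argmin(np.abs(time - t))),
                }
            )
    pd.DataFrame(rows).sort_values("time_s").to_csv(path, index=False)


def read_events_csv(path) -> GaitEventTable:
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in ("foot", "event_type", "time_s") if c not in df.columns]
    if missing:
        raise InputError(f"events CSV lacks columns {missing}")
    feet = {}
    for side in SIDES:
        sub = df[df["foot"] == side]
        feet[side] = FootEvents(
            heel_strikes=np.sort(sub[sub["event_type"] == "heel_strike"]["time_s"].to_numpy(float)),
            toe_offs=np.sort(sub[sub["event_type"] == "toe_off"]["time_s"].to_numpy(float)),
        )
    return GaitEventTable(left=feet["left"], right=feet["right"])
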