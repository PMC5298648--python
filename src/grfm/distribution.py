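"""Double-support distribution by the smooth transition assumption (STA).

During single support the stance foot carries the whole external wrench.
During double support the trailing foot's wrench is the total wrench frozen at
the leading foot's heel strike, scaled by six shape functions of normalized
double-support time tau in [0, 1] (three force, three moment components, in
the walking frame); the leading foot receives the remainder, so the per-sample
force and moment balances hold by construction.  Shape curves satisfy f(0)=1
(continuity at the contralateral heel strike) and f(1)=0 (smooth decay to
lift-off) and are represented as cubic splines through tabulated knots.

The package default is a raised-cosine transition, identical for all six
components; :func:`calibrate_sta` re-creates data-driven curves from any
per-foot force-plate corpus by normalizing, resampling and averaging the
trailing-foot curves over all second-double-support episodes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .dynamics import WrenchSeries, transfer_wrench
from .errors import InputError, NumericalError
from .events import GaitEventTable, double_support_episodes
from .kinematics import PointTrajectory

#: Component order of the six shape curves.
STA_COMPONENTS = ("fx", "fy", "fz", "mx", "my", "mz")


@dataclass
class STAFunction:
    """Six shape curves on normalized double-support time.

    ``values`` has shape (6, k): rows are anterior/lateral/vertical force and
    frontal/sagittal/transverse moment scale factors at the tau knots,
    expressed in the walking frame.
    """

    tau: np.ndarray  # (k,) knots in [0, 1]
    values: np.ndarray  # (6, k)
    source: str = "default"
    _splines: list[CubicSpline] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6, len(self.tau)):
            raise InputError("STA values must have shape (6, n_knots)")
        if self.tau[0] != 0.0 or self.tau[-1] != 1.0 or np.any(np.diff(self.tau) <= 0):
            raise InputError("STA knots must increase from 0 to 1")
        if np.max(np.abs(self.values[:, 0] - 1.0)) > 1e-9:
            raise InputError("STA curves must start at 1 (continuity at heel strike)")
        if np.max(np.abs(self.values[:, -1])) > 1e-9:
            raise InputError("STA curves must end at 0 (lift-off)")
        self._splines = [CubicSpline(self.tau, row) for row in self.values]

    def __call__(self, tau: np.ndarray | float) -> np.ndarray:
        """Evaluate the six scale factors; shape (6,) or (6, n)."""
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0.0) or np.any(tau > 1.0):
            raise InputError("normalized double-support time must lie in [0, 1]")
        out = np.stack([s(tau) for s in self._splines])
        # pin the endpoint invariants exactly
        out[..., tau == 0.0] = 1.0
        out[..., tau == 1.0] = 0.0
        return out


def evaluate_sta(sta: STAFunction, tau: np.ndarray | float) -> np.ndarray:
    """Functional alias for ``sta(tau)``."""
    return sta(tau)


def default_sta(n_knots: int = 51) -> STAFunction:
    """Raised-cosine transition ``f(tau) = (1 + cos(pi tau)) / 2`` for all six
    components: unit value and zero slope at heel strike, zero value and zero
    slope at toe-off, monotone in between."""
    tau = np.linspace(0.0, 1.0, n_knots)
    curve = 0.5 * (1.0 + np.cos(np.pi * tau))
    return STAFunction(tau=tau, values=np.tile(curve, (6, 1)), source="raised-cosine default")


def _ground_projection(points: np.ndarray) -> np.ndarray:
    proj = np.array(points, dtype=float, copy=True)
    proj[..., 2] = 0.0
    return proj


def distribute(
    total_w: WrenchSeries,
    events: GaitEventTable,
    sta: STAFunction,
    ankle_left: PointTrajectory | np.ndarray,
    ankle_right: PointTrajectory | np.ndarray,
) -> tuple[WrenchSeries, WrenchSeries]:
    """Split the walking-frame total wrench into left and right foot wrenches.

    ``ankle_left``/``ankle_right`` are the ankle-joint trajectories in the
    walking frame; their ground projections serve as per-foot moment reference
    points.  Returns (left, right) wrench series, each expressed about its own
    ankle projection, satisfying the per-sample force/moment balance exactly.
    """
    if total_w.frame != "w":
        raise InputError("distribute expects the total wrench in the walking frame")
    if np.max(np.abs(total_w.ref_point[:, 2])) > 1e-9:
        raise InputError("total wrench reference point must lie on the ground plane")
    time = total_w.time
    n = len(time)
    ap = {
        "left": _ground_projection(
            ankle_left.position if isinstance(ankle_left, PointTrajectory) else ankle_left
        ),
        "right": _ground_projection(
            ankle_right.position if isinstance(ankle_right, PointTrajectory) else ankle_right
        ),
    }
    stance = {side: events.stance_mask(side, time) for side in ("left", "right")}
    force = {side: np.zeros((n, 3)) for side in ("left", "right")}
    moment = {side: np.zeros((n, 3)) for side in ("left", "right")}

    # single support: the stance foot takes the whole wrench about its own
    # ankle projection, recomputed each sample
    for side in ("left", "right"):
        only = stance[side] & ~stance["left" if side == "right" else "right"]
        if np.any(only):
            at_ap = transfer_wrench(total_w, ap[side])
            force[side][only] = at_ap.force[only]
            moment[side][only] = at_ap.moment[only]

    # double support: trailing foot scaled by the STA, leading by subtraction
    both = stance["left"] & stance["right"]
    covered = np.zeros(n, dtype=bool)
    for ep in double_support_episodes(events):
        if ep.end <= ep.start:
            raise NumericalError(f"degenerate double-support phase at t={ep.start:g} s")
        sel = both & (time >= ep.start) & (time < ep.end)
        if not np.any(sel):
            continue
        idx = np.flatnonzero(sel)
        covered[idx] = True
        i0 = int(np.searchsorted(time, ep.start))
        trail, lead = ep.trailing, ep.leading
        tap = ap[trail]
        total_at_tap = transfer_wrench(total_w, tap)
        tau = (time[idx] - ep.start) / (ep.end - ep.start)
        factors = sta(tau)  # (6, len(idx))
        anchor_f = total_at_tap.force[i0]
        anchor_m = total_at_tap.moment[i0]
        force[trail][idx] = anchor_f * factors[0:3].T
        moment[trail][idx] = anchor_m * factors[3:6].T
        force[lead][idx] = total_at_tap.force[idx] - force[trail][idx]
        lead_m_at_tap = total_at_tap.moment[idx] - moment[trail][idx]
        moment[lead][idx] = lead_m_at_tap + np.cross(
            tap[idx] - ap[lead][idx], force[lead][idx]
        )

    # both feet planted outside any gait episode (standing): split evenly,
    # preserving the balance; never taken during normal walking
    rest = np.flatnonzero(both & ~covered)
    if len(rest):
        for side in ("left", "right"):
            at_ap = transfer_wrench(total_w, ap[side])
            force[side][rest] = 0.5 * at_ap.force[rest]
            moment[side][rest] = 0.5 * at_ap.moment[rest]

    left = WrenchSeries(time, force["left"], moment["left"], ap["left"], frame="w")
    right = WrenchSeries(time, force["right"], moment["right"], ap["right"], frame="w")
    return left, right


def calibrate_sta(
    left_wrench: WrenchSeries,
    right_wrench: WrenchSeries,
    events: GaitEventTable,
    n_knots: int = 51,
    anchor_tol: float = 1e-9,
) -> STAFunction:
    """Re-create the six shape curves from measured per-foot wrenches.

    For every double-support episode the trailing foot's six components are
    normalized by their value at the leading heel strike, resampled onto the
    normalized-time grid and averaged across episodes; endpoints are clamped to
    1 and 0 and a cubic spline is fitted through the mean curve.  Episodes with
    a vanishing component at the heel strike are excluded with a warning.
    """
    wrenches = {"left": left_wrench, "right": right_wrench}
    tau_grid = np.linspace(0.0, 1.0, n_knots)
    curves: list[np.ndarray] = []
    for ep in double_support_episodes(events):
        w = wrenches[ep.trailing]
        time = w.time
        sel = (time >= ep.start) & (time <= ep.end)
        if np.count_nonzero(sel) < 3:
            continue
        i0 = int(np.searchsorted(time, ep.start))
        comp = np.hstack([w.force, w.moment])  # (n, 6)
        anchors = comp[i0]
        if np.min(np.abs(anchors)) < anchor_tol:
            warnings.warn(
                f"double-support episode at t={ep.start:g} s excluded: zero wrench "
                "component at heel strike",
                stacklevel=2,
            )
            continue
        tau = (time[sel] - ep.start) / (ep.end - ep.start)
        normalized = comp[sel] / anchors
        resampled = np.stack(
            [np.interp(tau_grid, tau, normalized[:, k]) for k in range(6)]
        )
        curves.append(resampled)
    if not curves:
        raise InputError("no usable double-support episodes for STA calibration")
    mean_curve = np.mean(curves, axis=0)
    mean_curve[:, 0] = 1.0
    mean_curve[:, -1] = 0.0
    return STAFunction(tau=tau_grid, values=mean_curve, source=f"calibrated ({len(curves)} episodes)")


def write_sta_csv(sta: STAFunction, path: str | Path, meta_path: str | Path | None = None) -> None:
    df = pd.DataFrame({"tau": sta.tau, **{c: sta.values[i] for i, c in enumerate(STA_COMPONENTS)}})
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {"source": sta.source, "frame": "walking", "components": list(STA_COMPONENTS)}
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))


def read_sta_csv(path: str | Path) -> STAFunction:
    df = pd.read_csv(Path(path))
    missing = [c for c in ("tau",) + STA_COMPONENTS if c not in df.columns]
    if missing:
        raise InputError(f"STA curve file lacks columns {missing}")
    meta_path = Path(path).with_suffix(".json")
    source = "file"
    if meta_path.exists():
        source = json.loads(meta_path.read_text()).get("source", "file")
    values = np.stack([df[c].to_numpy(float) for c in STA_COMPONENTS])
    return STAFunction(tau=df["tau"].to_numpy(float), values=values, source=source)
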