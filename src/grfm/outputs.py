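"""Centre of pressure, frictional torque and the standard normalisations.

With the per-foot wrench expressed in the walking frame about the ankle-joint
ground projection, the centre of pressure relative to that projection is
``COPx = -My / Fz``, ``COPy = Mx / Fz`` (on the ground, ``COPz = 0``), valid
where the vertical force exceeds a 5 N threshold.  The frictional torque is
the vertical moment left after moving the wrench to the COP:
``T_F = Mz - COPx Fy + COPy Fx``.

Forces are normalized to body weight (N/BW) and moments to body weight times
body height (N m / (BW BH)); curves are resampled onto a uniform 0-100 %
gait-cycle grid (101 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import STANDARD_GRAVITY
from .dynamics import WrenchSeries
from .errors import InputError


@dataclass
class CopSeries:
    time: np.ndarray  # (n,) s
    cop: np.ndarray  # (n, 2) m (anterior, lateral) relative to the ankle projection
    frictional_torque: np.ndarray  # (n,) N m
    valid_mask: np.ndarray  # (n,) bool, vertical force above threshold


def compute_cop(wrench_w: WrenchSeries, fz_threshold_n: float = 5.0) -> CopSeries:
    """COP and frictional torque from a per-foot walking-frame wrench.

    Samples with vertical force at or below the threshold are masked (NaN).
    """
    if wrench_w.frame != "w":
        raise InputError("COP is defined in the walking frame")
    if np.max(np.abs(wrench_w.ref_point[:, 2])) > 1e-9:
        raise InputError("wrench must be expressed about a point on the ground plane")
    fx, fy, fz = wrench_w.force.T
    mx, my, mz = wrench_w.moment.T
    valid = fz > fz_threshold_n
    cop = np.full((len(fz), 2), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        cop[valid, 0] = -my[valid] / fz[valid]
        cop[valid, 1] = mx[valid] / fz[valid]
    torque = np.full(len(fz), np.nan)
    torque[valid] = compute_frictional_torque(
        mz[valid], cop[valid, 0], cop[valid, 1], fx[valid], fy[valid]
    )
    return CopSeries(wrench_w.time, cop, torque, valid)


def compute_frictional_torque(
    mz: np.ndarray, cop_x: np.ndarray, cop_y: np.ndarray, fx: np.ndarray, fy: np.ndarray
) -> np.ndarray:
    """Vertical moment about the COP: ``T_F = Mz - COPx Fy + COPy Fx``."""
    return mz - cop_x * fy + cop_y * fx


def normalize_wrench(
    wrench: WrenchSeries, body_mass_kg: float, height_m: float, gravity: float = STANDARD_GRAVITY
) -> WrenchSeries:
    """Express forces in body-weight and moments in body-weight-times-height units."""
    if body_mass_kg <= 0 or height_m <= 0:
        raise InputError("mass and height must be positive")
    bw = body_mass_kg * gravity
    return WrenchSeries(
        wrench.time,
        wrench.force / bw,
        wrench.moment / (bw * height_m),
        wrench.ref_point,
        wrench.frame,
    )


def time_normalize(
    values: np.ndarray,
    time: np.ndarray,
    cycle: tuple[float, float],
    n_points: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a curve onto the uniform percent-of-gait-cycle grid.

    ``cycle`` is bounded by two consecutive ipsilateral heel strikes.  Returns
    (percent grid, resampled values); ``values`` may be (n,) or (n, k).
    """
    t0, t1 = cycle
    if t1 <= t0:
        raise InputError("gait cycle must have positive duration")
    sel = (time >= t0) & (time <= t1)
    if np.count_nonzero(sel) < 3:
        raise InputError("gait cycle spans fewer than 3 samples")
    percent = np.linspace(0.0, 100.0, n_points)
    target_t = t0 + (t1 - t0) * percent / 100.0
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        out = np.interp(target_t, time[sel], values[sel])
    else:
        out = np.column_stack(
            [np.interp(target_t, time[sel], values[sel, k]) for k in range(values.shape[1])]
        )
    return percent, out
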