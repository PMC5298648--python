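"""Accuracy metrics for predicted versus measured GRF&M curves.

The protocol compares curves with the absolute RMSE, the relative RMSE
(RMSE divided by the mean of the two curves' peak-to-peak ranges, in percent),
Pearson's correlation with categorical bands (weak <= 0.35 < moderate <= 0.67
< strong <= 0.9 < excellent), and the Sprague & Geers (2004) integral
magnitude/phase discrepancies

    M = (sqrt(psi_cc / psi_mm) - 1) * 100
    P = arccos(psi_mc / sqrt(psi_mm psi_cc)) / pi * 100

with psi_ab the mean of a*b over the comparison window (m measured,
c predicted).  Metrics are additionally evaluated on the DS1/DS2/SS sub-phases
and on named early/middle/late-stance peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError
from .events import (
    PHASE_DS1,
    PHASE_DS2,
    PHASE_SS_CONTRA,
    PHASE_SS_IPSI,
    GaitEventTable,
    label_phases,
)

FORCE_COMPONENTS = ("anterior", "lateral", "vertical")
MOMENT_COMPONENTS = ("frontal", "sagittal", "transverse")
COMPONENTS = FORCE_COMPONENTS + MOMENT_COMPONENTS

CORRELATION_BANDS = ((0.35, "weak"), (0.67, "moderate"), (0.9, "strong"))


def rmse_rrmse(predicted: np.ndarray, measured: np.ndarray) -> tuple[float, float]:
    """Absolute RMSE and RMSE relative to the mean peak-to-peak range (%).

    When both curves are flat the relative error is undefined and returned as
    NaN with a warning.
    """
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape:
        raise InputError("curves must share a sampling grid")
    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    mean_range = 0.5 * (np.ptp(predicted) + np.ptp(measured))
    if mean_range == 0.0:
        warnings.warn("both curves are constant; relative RMSE undefined", stacklevel=2)
        return rmse, float("nan")
    return rmse, 100.0 * rmse / mean_range


def correlation_category(rho: float) -> str:
    for upper, name in CORRELATION_BANDS:
        if rho <= upper:
            return name
    return "excellent"


def pearson_with_category(predicted: np.ndarray, measured: np.ndarray) -> tuple[float, str]:
    """Sample Pearson correlation and its categorical band."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if np.ptp(predicted) == 0.0 or np.ptp(measured) == 0.0:
        warnings.warn("constant curve; correlation undefined", stacklevel=2)
        return float("nan"), "undefined"
    rho = float(np.corrcoef(predicted, measured)[0, 1])
    return rho, correlation_category(rho)


def sprague_geers(predicted: np.ndarray, measured: np.ndarray) -> tuple[float, float]:
    """Magnitude and phase percentage discrepancies (predicted vs measured)."""
    c = np.asarray(predicted, float)
    m = np.asarray(measured, float)
    if c.shape != m.shape:
        raise InputError("curves must share a sampling grid")
    psi_mm = float(np.mean(m * m))
    psi_cc = float(np.mean(c * c))
    psi_mc = float(np.mean(m * c))
    if psi_mm == 0.0 or psi_cc == 0.0:
        raise NumericalError("zero-energy curve; magnitude/phase metrics undefined")
    magnitude = (np.sqrt(psi_cc / psi_mm) - 1.0) * 100.0
    phase = np.arccos(np.clip(psi_mc / np.sqrt(psi_mm * psi_cc), -1.0, 1.0)) / np.pi * 100.0
    return float(magnitude), float(phase)


def curve_metrics(predicted: np.ndarray, measured: np.ndarray) -> dict[str, float | str]:
    rmse, rrmse = rmse_rrmse(predicted, measured)
    rho, category = pearson_with_category(predicted, measured)
    m_pct, p_pct = sprague_geers(predicted, measured)
    return {
        "rho": rho,
        "category": category,
        "rmse": rmse,
        "rrmse_percent": rrmse,
        "M_percent": m_pct,
        "P_percent": p_pct,
    }


def subphase_metrics(
    predicted: dict[str, np.ndarray],
    measured: dict[str, np.ndarray],
    time: np.ndarray,
    events: GaitEventTable,
    reference_foot: str = "right",
) -> pd.DataFrame:
    """rho/RMSE/rRMSE per component on the full cycle and DS1/DS2/SS slices.

    ``predicted``/``measured`` map component names to per-sample curves on the
    common grid.  Empty sub-phases are omitted with a warning.
    """
    labels = label_phases(events, time, reference_foot)
    scopes = {
        "full": labels != "",
        PHASE_DS1: labels == PHASE_DS1,
        PHASE_DS2: labels == PHASE_DS2,
        "SS": (labels == PHASE_SS_IPSI) | (labels == PHASE_SS_CONTRA),
    }
    rows = []
    for scope, mask in scopes.items():
        if not np.any(mask):
            warnings.warn(f"sub-phase {scope!r} contains no samples; omitted", stacklevel=2)
            continue
        for comp in predicted:
            rmse, rrmse = rmse_rrmse(predicted[comp][mask], measured[comp][mask])
            rho, category = pearson_with_category(predicted[comp][mask], measured[comp][mask])
            rows.append(
                {
                    "component": comp,
                    "scope": scope,
                    "rho": rho,
                    "category": category,
                    "rmse": rmse,
                    "rrmse_percent": rrmse,
                }
            )
    return pd.DataFrame(rows)


#: Named peaks sought in thirds of the stance phase (component, phase, extremum).
PEAK_DEFINITIONS = (
    ("lateral", "ES", "max"),
    ("vertical", "ES", "max"),
    ("anterior", "ES", "min"),
    ("vertical", "MS", "min"),
    ("anterior", "LS", "max"),
    ("lateral", "LS", "max"),
    ("vertical", "LS", "max"),
    ("transverse", "LS", "max"),
    ("frontal", "LS", "min"),
    ("sagittal", "LS", "min"),
)

_PHASE_BOUNDS = {"ES": (0.0, 1.0 / 3.0), "MS": (1.0 / 3.0, 2.0 / 3.0), "LS": (2.0 / 3.0, 1.0)}


def peak_analysis(
    predicted: dict[str, np.ndarray],
    measured: dict[str, np.ndarray],
    time: np.ndarray,
    stance_window: tuple[float, float],
) -> pd.DataFrame:
    """Early/middle/late-stance peak differences (predicted minus measured).

    ``stance_window`` bounds one stance phase; each named extremum is located
    independently in both curves inside its third of stance.  The relative
    difference uses the measured extremum as denominator, so a negative entry
    on a maximum means underestimation.
    """
    t0, t1 = stance_window
    if t1 <= t0:
        raise InputError("stance window must have positive duration")
    frac = (time - t0) / (t1 - t0)
    rows = []
    for comp, phase, kind in PEAK_DEFINITIONS:
        if comp not in predicted:
            continue
        lo, hi = _PHASE_BOUNDS[phase]
        mask = (frac > lo) & (frac <= hi)
        if not np.any(mask):
            raise InputError(f"stance sub-phase {phase} contains no samples")
        pick = np.max if kind == "max" else np.min
        peak_pred = float(pick(predicted[comp][mask]))
        peak_meas = float(pick(measured[comp][mask]))
        diff = peak_pred - peak_meas
        rows.append(
            {
                "component": comp,
                "phase": phase,
                "extremum": kind,
                "predicted": peak_pred,
                "measured": peak_meas,
                "abs_difference": diff,
                "rel_difference_percent": 100.0 * diff / peak_meas if peak_meas != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """Full-cycle metrics, sub-phase slices and the peak table."""

    per_component: pd.DataFrame  # component x (rho, category, rmse, rrmse, M, P)
    subphases: pd.DataFrame
    peaks: pd.DataFrame
    n_cycles: int = 0

    def to_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_component.to_csv(directory / "metrics_full_cycle.csv", index=False)
        self.subphases.to_csv(directory / "metrics_subphases.csv", index=False)
        self.peaks.to_csv(directory / "metrics_peaks.csv", index=False)
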