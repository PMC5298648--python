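"""End-to-end prediction pipeline and the two sensitivity sweeps.

``run_predict`` chains the stages: ingest and validate kinematics, fill
angular accelerations, low-pass filter the dynamic channels, derive the
walking frame and the pelvis-speed threshold, detect gait events, evaluate the
Newton-Euler total wrench, rotate it into the walking frame, distribute it
over the feet with the smooth-transition curves and derive COP and frictional
torque.  ``run_evaluate`` compares a prediction against reference per-foot
wrenches with the full metric suite; ``run_sweep`` re-runs the prediction over
a cut-off-frequency or threshold-multiplier grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import body as body_mod
from .body import BodyModel, load_deleva_table, scale_body
from .distribution import STAFunction, default_sta, distribute, read_sta_csv
from .dynamics import (
    WrenchSeries,
    rotate_wrench,
    total_external_moment,
    write_wrench_csv,
)
from .errors import InputError
from .events import (
    GaitEventTable,
    ThresholdConfig,
    compute_vth,
    detect_events,
    detect_events_forceplate,
    gait_cycles,
    write_events_csv,
)
from .kinematics import (
    FramePair,
    PointTrajectory,
    SegmentKinematicsSeries,
    differentiate,
    differentiate_angular_velocity,
    filter_channel,
    lowpass_filter,
    walking_frame,
)
from .metrics import (
    COMPONENTS,
    MetricReport,
    correlation_category,
    curve_metrics,
    peak_analysis,
    subphase_metrics,
)
from .outputs import CopSeries, compute_cop, normalize_wrench, time_normalize

log = logging.getLogger(__name__)

REQUIRED_POINTS = (
    "pelvis",
    "heel_left",
    "heel_right",
    "toe_left",
    "toe_right",
    "ankle_left",
    "ankle_right",
)


@dataclass
class PipelineConfig:
    """Every tunable of the prediction pipeline, defaulting to the reference
    protocol values (6 Hz second-order zero-phase filter, 0.6/1.9 threshold
    multipliers, 5 N force threshold, 101-point cycle grid)."""

    cutoff_hz: float | None = 6.0
    filter_order: int = 2
    heel_multiplier: float = 0.6
    toe_multiplier: float = 1.9
    fz_threshold_n: float = 5.0
    gravity: float = 9.81
    n_points: int = 101
    min_displacement_m: float = 0.5
    min_gap_s: float = 0.05
    sta_curves: str = "default"  # "default" or a path to an STA CSV
    seed: int = 0

    def resolve_sta(self) -> STAFunction:
        if self.sta_curves == "default":
            return default_sta()
        return read_sta_csv(self.sta_curves)


@dataclass
class PredictionResult:
    time: np.ndarray
    frame: FramePair
    v_th: float
    events: GaitEventTable
    total_w: WrenchSeries
    left: WrenchSeries
    right: WrenchSeries
    cop_left: CopSeries
    cop_right: CopSeries
    config: PipelineConfig

    def foot(self, side: str) -> WrenchSeries:
        return self.left if side == "left" else self.right


def _point_speeds(
    points: dict[str, PointTrajectory],
    time: np.ndarray,
    config: PipelineConfig,
) -> dict[str, PointTrajectory]:
    """Fill missing point velocities by differentiating (and filtering) positions."""
    out = {}
    fs = 1.0 / float(np.mean(np.diff(time)))
    for name, p in points.items():
        if p.velocity is not None:
            out[name] = p
            continue
        vel = differentiate(p.position, time)
        if config.cutoff_hz is not None:
            vel = filter_channel(vel, config.cutoff_hz, fs, config.filter_order)
        out[name] = PointTrajectory(position=p.position, velocity=vel)
    return out


def run_predict(
    kinematics: SegmentKinematicsSeries,
    points: dict[str, PointTrajectory],
    body: BodyModel,
    config: PipelineConfig | None = None,
    sta: STAFunction | None = None,
) -> PredictionResult:
    """Predict per-foot GRF&M from segment kinematics and tracked points."""
    config = config or PipelineConfig()
    missing = [p for p in REQUIRED_POINTS if p not in points]
    if missing:
        raise InputError(f"missing tracked points: {missing}")
    kinematics.validate()
    if any(seg.ang_acc is None for seg in kinematics.segments.values()):
        kinematics = differentiate_angular_velocity(kinematics)
    if config.cutoff_hz is not None:
        kinematics = lowpass_filter(kinematics, config.cutoff_hz, config.filter_order)
    time = kinematics.time

    points = _point_speeds(points, time, config)
    frame = walking_frame(points["pelvis"].position, config.min_displacement_m)
    v_th = compute_vth(points["pelvis"].velocity)
    threshold = ThresholdConfig(
        v_th=v_th,
        heel_multiplier=config.heel_multiplier,
        toe_multiplier=config.toe_multiplier,
        min_gap_s=config.min_gap_s,
    )
    log.info("walking frame yaw %.2f deg, v_th %.3f m/s", np.rad2deg(frame.yaw), v_th)
    events = detect_events(
        time,
        {s: points[f"heel_{s}"].speed() for s in ("left", "right")},
        {s: points[f"toe_{s}"].speed() for s in ("left", "right")},
        threshold,
    )

    body = BodyModel(
        segments=body.segments,
        total_mass=body.total_mass,
        height=body.height,
        gravity=np.array([0.0, 0.0, -abs(config.gravity)]),
    )
    total_g = total_external_moment(body, kinematics, np.zeros(3))
    total_w = rotate_wrench(total_g, frame)
    ankle_w = {
        side: frame.to_walking(points[f"ankle_{side}"].position) for side in ("left", "right")
    }
    left, right = distribute(
        total_w, events, sta or config.resolve_sta(), ankle_w["left"], ankle_w["right"]
    )
    cop_left = compute_cop(left, config.fz_threshold_n)
    cop_right = compute_cop(right, config.fz_threshold_n)
    return PredictionResult(
        time=time,
        frame=frame,
        v_th=v_th,
        events=events,
        total_w=total_w,
        left=left,
        right=right,
        cop_left=cop_left,
        cop_right=cop_right,
        config=config,
    )


# ---------------------------------------------------------------------------
# Evaluation


def _component_curves(wrench: WrenchSeries) -> dict[str, np.ndarray]:
    fx, fy, fz = wrench.force.T
    mx, my, mz = wrench.moment.T
    return {
        "anterior": fx,
        "lateral": fy,
        "vertical": fz,
        "frontal": mx,
        "sagittal": my,
        "transverse": mz,
    }


def run_evaluate(
    result: PredictionResult,
    reference_left: WrenchSeries,
    reference_right: WrenchSeries,
    body: BodyModel,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Compare predicted and reference per-foot wrenches.

    Reference gait events come from the 5 N rule on the reference vertical
    forces.  Full-cycle metrics are computed per gait cycle on the normalized
    0-100 % grid and averaged across cycles; sub-phase and peak metrics follow
    the DS1/DS2/SS and early/middle/late-stance definitions.
    """
    config = config or result.config
    refs = {"left": reference_left, "right": reference_right}
    time = result.time
    if len(reference_left.time) != len(time) or not np.allclose(reference_left.time, time):
        raise InputError("prediction and reference must share a time base")
    ref_events = detect_events_forceplate(
        time,
        {s: refs[s].force[:, 2] for s in ("left", "right")},
        config.fz_threshold_n,
    )

    rows = []
    peak_frames = []
    n_cycles = 0
    for side in ("left", "right"):
        pred_n = normalize_wrench(result.foot(side), body.total_mass, body.height, config.gravity)
        ref_n = normalize_wrench(refs[side], body.total_mass, body.height, config.gravity)
        pred_curves = _component_curves(pred_n)
        ref_curves = _component_curves(ref_n)
        cycles = gait_cycles(ref_events, side)
        if not cycles:
            continue
        n_cycles += len(cycles)
        per_cycle = {comp: [] for comp in COMPONENTS}
        for cycle in cycles:
            for comp in COMPONENTS:
                _, pred_c = time_normalize(pred_curves[comp], time, cycle, config.n_points)
                _, ref_c = time_normalize(ref_curves[comp], time, cycle, config.n_points)
                per_cycle[comp].append(curve_metrics(pred_c, ref_c))
        for comp in COMPONENTS:
            metrics = per_cycle[comp]
            agg = {"foot": side, "component": comp, "n_cycles": len(metrics)}
            for key in ("rho", "rmse", "rrmse_percent", "M_percent", "P_percent"):
                vals = np.array([m[key] for m in metrics], dtype=float)
                agg[key] = float(np.nanmean(vals))
                agg[f"{key}_sd"] = float(np.nanstd(vals))
            agg["category"] = correlation_category(agg["rho"])
            rows.append(agg)

        # peaks: one stance window per cycle (heel strike to own toe-off)
        for t_hs, _ in cycles:
            to_later = ref_events.foot(side).toe_offs
            to_after = to_later[to_later > t_hs]
            if len(to_after) == 0:
                continue
            window = (t_hs, float(to_after[0]))
            pk = peak_analysis(pred_curves, ref_curves, time, window)
            pk.insert(0, "foot", side)
            peak_frames.append(pk)

    subphase_frames = []
    for side in ("left", "right"):
        pred_n = normalize_wrench(result.foot(side), body.total_mass, body.height, config.gravity)
        ref_n = normalize_wrench(refs[side], body.total_mass, body.height, config.gravity)
        try:
            sp = subphase_metrics(
                _component_curves(pred_n), _component_curves(ref_n), time, ref_events, side
            )
        except InputError:
            continue
        sp.insert(0, "foot", side)
        subphase_frames.append(sp)

    peaks = pd.concat(peak_frames, ignore_index=True) if peak_frames else pd.DataFrame()
    if not peaks.empty:
        peaks = (
            peaks.groupby(["foot", "component", "phase", "extremum"], sort=False)
            .mean(numeric_only=True)
            .reset_index()
        )
    subphases = (
        pd.concat(subphase_frames, ignore_index=True) if subphase_frames else pd.DataFrame()
    )
    if n_cycles == 0:
        raise InputError("no overlapping gait cycles between prediction and reference")
    return MetricReport(
        per_component=pd.DataFrame(rows),
        subphases=subphases,
        peaks=peaks,
        n_cycles=n_cycles,
    )


# ---------------------------------------------------------------------------
# Sensitivity sweeps


def rmse_by_component(pred: WrenchSeries, ref: WrenchSeries) -> dict[str, float]:
    out = {}
    pc, rc = _component_curves(pred), _component_curves(ref)
    for comp in COMPONENTS:
        out[comp] = float(np.sqrt(np.mean((pc[comp] - rc[comp]) ** 2)))
    out["norm_grf"] = float(np.sqrt(np.mean(np.sum((pred.force - ref.force) ** 2, axis=1))))
    out["norm_grm"] = float(np.sqrt(np.mean(np.sum((pred.moment - ref.moment) ** 2, axis=1))))
    return out


def run_sweep(
    kind: str,
    kinematics: SegmentKinematicsSeries,
    points: dict[str, PointTrajectory],
    body: BodyModel,
    reference_left: WrenchSeries,
    reference_right: WrenchSeries,
    base_config: PipelineConfig | None = None,
    grid: list[float] | None = None,
    reference_events: GaitEventTable | None = None,
) -> pd.DataFrame:
    """Cut-off-frequency or event-threshold sensitivity analysis.

    ``kind='cutoff'``: re-run the prediction per cut-off frequency and report
    the percent change in per-component RMSE relative to the baseline cut-off.
    ``kind='threshold'``: scale both multipliers by the grid factors and report
    mean absolute event-time errors against the reference events.
    """
    base_config = base_config or PipelineConfig()
    refs = {"left": reference_left, "right": reference_right}
    if kind == "cutoff":
        grid = grid or [3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        baseline = None
        rows = []
        for fc in grid:
            cfg = PipelineConfig(**{**asdict(base_config), "cutoff_hz": fc})
            res = run_predict(kinematics, points, body, cfg)
            rmse = {}
            for side in ("left", "right"):
                for comp, val in rmse_by_component(res.foot(side), refs[side]).items():
                    rmse[comp] = rmse.get(comp, 0.0) + 0.5 * val
            rows.append({"cutoff_hz": fc, **rmse})
            if fc == base_config.cutoff_hz:
                baseline = rmse
        if baseline is None:
            res = run_predict(kinematics, points, body, base_config)
            baseline = {}
            for side in ("left", "right"):
                for comp, val in rmse_by_component(res.foot(side), refs[side]).items():
                    baseline[comp] = baseline.get(comp, 0.0) + 0.5 * val
        table = []
        for row in rows:
            entry = {"cutoff_hz": row["cutoff_hz"]}
            for comp, val in row.items():
                if comp == "cutoff_hz":
                    continue
                entry[f"{comp}_rmse_change_percent"] = (
                    100.0 * (val - baseline[comp]) / baseline[comp] if baseline[comp] else np.nan
                )
            table.append(entry)
        return pd.DataFrame(table)

    if kind == "threshold":
        grid = grid or [0.9, 1.0, 1.1]
        if reference_events is None:
            ref_events = detect_events_forceplate(
                kinematics.time,
                {s: refs[s].force[:, 2] for s in ("left", "right")},
                base_config.fz_threshold_n,
            )
        else:
            ref_events = reference_events
        rows = []
        for factor in grid:
            cfg = PipelineConfig(
                **{
                    **asdict(base_config),
                    "heel_multiplier": base_config.heel_multiplier * factor,
                    "toe_multiplier": base_config.toe_multiplier * factor,
                }
            )
            res = run_predict(kinematics, points, body, cfg)
            errs = {"heel_strike": [], "toe_off": []}
            for side in ("left", "right"):
                for kind_name, pred_t, ref_t in (
                    ("heel_strike", res.events.foot(side).heel_strikes,
                     ref_events.foot(side).heel_strikes),
                    ("toe_off", res.events.foot(side).toe_offs, ref_events.foot(side).toe_offs),
                ):
                    for t in ref_t:
                        if len(pred_t):
                            errs[kind_name].append(np.min(np.abs(pred_t - t)))
            rows.append(
                {
                    "multiplier_factor": factor,
                    "heel_strike_mean_error_ms": 1e3 * float(np.mean(errs["heel_strike"]))
                    if errs["heel_strike"]
                    else np.nan,
                    "toe_off_mean_error_ms": 1e3 * float(np.mean(errs["toe_off"]))
                    if errs["toe_off"]
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    raise InputError(f"unknown sweep kind {kind!r} (expected 'cutoff' or 'threshold')")


# ---------------------------------------------------------------------------
# File-level helpers (used by the CLI)


def load_anthropometry(path: str | Path) -> BodyModel:
    """Build a body model from an anthropometry JSON file."""
    try:
        cfg = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read anthropometry config {path}: {exc}") from exc
    for key in ("total_mass_kg", "height_m", "segment_lengths_m"):
        if key not in cfg:
            raise InputError(f"anthropometry config lacks key {key!r}")
    return scale_body(
        load_deleva_table(),
        cfg["total_mass_kg"],
        cfg["height_m"],
        cfg["segment_lengths_m"],
        instrumentation=cfg.get("instrumentation_kg"),
        gravity=cfg.get("gravity", body_mod.STANDARD_GRAVITY),
    )


def write_prediction(result: PredictionResult, body: BodyModel, outdir: str | Path) -> None:
    """Write per-foot wrench/COP CSVs, the total wrench, events and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_wrench_csv(result.total_w, outdir / "total_wrench.csv")
    for side in ("left", "right"):
        wrench = result.foot(side)
        cop = getattr(result, f"cop_{side}")
        write_wrench_csv(wrench, outdir / f"grfm_{side}.csv")
        df = pd.DataFrame(
            {
                "time": result.time,
                "cop_anterior_m": cop.cop[:, 0],
                "cop_lateral_m": cop.cop[:, 1],
                "frictional_torque_nm": cop.frictional_torque,
                "valid": cop.valid_mask.astype(int),
            }
        )
        df.to_csv(outdir / f"cop_{side}.csv", index=False)
    write_events_csv(result.events, result.time, outdir / "events.csv")
    manifest = {
        "config": asdict(result.config),
        "v_th_mps": result.v_th,
        "walking_frame_yaw_deg": float(np.rad2deg(result.frame.yaw)),
        "body_total_mass_kg": body.total_mass,
        "body_height_m": body.height,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
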