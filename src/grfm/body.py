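"""Scaled 16-segment rigid-body model from subject anthropometry.

The body is modelled as 16 rigid segments (head, upper/middle trunk, pelvis and
left/right instances of upper arm, forearm, hand, upper leg, lower leg, foot).
Per-segment mass fractions, longitudinal centre-of-mass positions and radii of
gyration follow the adjusted Zatsiorsky-Seluyanov ratios tabulated by De Leva
(1996), shipped as package data.

Segment frames are right-handed with the longitudinal axis ``z`` pointing from
the proximal to the distal end; the CoM offset is applied along it.  Wearable
instrumentation (IMUs, communication pack, battery) is handled by subtracting
its total mass before applying the mass fractions and then adding each
component back onto the segment carrying it; the resulting segment mass feeds
the radius-of-gyration inertia while the gyration radii themselves are left
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

#: Rows of the anthropometric table (single entry per bilateral segment).
TABLE_ROWS = (
    "head",
    "upper_trunk",
    "middle_trunk",
    "pelvis",
    "upper_arm",
    "forearm",
    "hand",
    "upper_leg",
    "lower_leg",
    "foot",
)

#: Segments that occur once in the 16-segment model.
AXIAL_SEGMENTS = ("head", "upper_trunk", "middle_trunk", "pelvis")

#: Segments instantiated for both sides.
BILATERAL_SEGMENTS = ("upper_arm", "forearm", "hand", "upper_leg", "lower_leg", "foot")

#: Canonical names of the 16 segments.
SEGMENT_NAMES: tuple[str, ...] = AXIAL_SEGMENTS + tuple(
    f"{s}_{side}" for s in BILATERAL_SEGMENTS for side in ("l", "r")
)

STANDARD_GRAVITY = 9.81  # m/s^2


def table_row(segment: str) -> str:
    """Map a segment instance name (e.g. ``foot_l``) to its table row (``foot``)."""
    if segment.endswith(("_l", "_r")):
        return segment[:-2]
    return segment


@dataclass(frozen=True)
class SegmentParams:
    """Anthropometric ratios of one table row.

    All quantities are dimensionless fractions of net body mass (``mass_fraction``)
    or of segment length (CoM position and radii of gyration).
    """

    name: str
    mass_fraction: float
    com_longitudinal_fraction: float
    gyration_fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = (self.mass_fraction, self.com_longitudinal_fraction, *self.gyration_fractions)
        if not all(0.0 < v < 1.0 for v in values):
            raise ConfigurationError(f"segment {self.name!r}: fractions must lie in (0, 1)")


def load_deleva_table() -> dict[str, SegmentParams]:
    """Load the per-segment anthropometric ratios shipped with the package.

    Returns one entry per table row (bilateral segments appear once); percent
    values in the file are converted to fractions.
    """
    with resources.files("grfm.data").joinpath("deleva_16seg.csv").open() as fh:
        df = pd.read_csv(fh)
    table: dict[str, SegmentParams] = {}
    for row in df.itertuples(index=False):
        table[row.segment] = SegmentParams(
            name=row.segment,
            mass_fraction=row.mass_pct / 100.0,
            com_longitudinal_fraction=row.com_pct / 100.0,
            gyration_fractions=(row.rx_pct / 100.0, row.ry_pct / 100.0, row.rz_pct / 100.0),
        )
    return table


def segment_inertia(
    mass_kg: float, length_m: float, gyration_fractions: tuple[float, float, float]
) -> np.ndarray:
    """Diagonal inertia tensor about the segment CoM, ``J_kk = m (r_k L)^2``.

    ``gyration_fractions`` are radii of gyration expressed as fractions of the
    segment length.  A zero fraction yields a zero diagonal entry (point-mass
    limit along that axis).
    """
    if mass_kg <= 0 or length_m <= 0:
        raise InputError("segment mass and length must be positive")
    radii = np.asarray(gyration_fractions, dtype=float) * length_m
    return np.diag(mass_kg * radii**2)


@dataclass
class ScaledSegment:
    """One segment of the scaled model, in its own (proximal-origin) frame."""

    name: str
    mass: float
    length: float
    com_offset_local: np.ndarray  # (3,) m, proximal origin -> CoM
    inertia_com_local: np.ndarray  # (3,3) kg m^2 about CoM
    endpoint_offsets_local: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InputError(f"segment {self.name!r}: mass must be positive")
        J = np.asarray(self.inertia_com_local, dtype=float)
        if not np.allclose(J, J.T, atol=1e-12):
            raise InputError(f"segment {self.name!r}: inertia tensor must be symmetric")
        if np.min(np.linalg.eigvalsh(J)) < -1e-12:
            raise InputError(f"segment {self.name!r}: inertia tensor must be PSD")


@dataclass
class BodyModel:
    """Scaled 16-segment model plus the gravity vector used in the dynamics."""

    segments: dict[str, ScaledSegment]
    total_mass: float  # kg, measured mass (net body + instrumentation)
    height: float  # m
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -STANDARD_GRAVITY]))

    @property
    def segment_names(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def mass_check(self, tol: float = 1e-6) -> float:
        """Return the mass-conservation residual |sum(segment masses) - total|."""
        residual = abs(sum(s.mass for s in self.segments.values()) - self.total_mass)
        if residual > tol:
            raise NumericalErrorFromMass(residual)
        return residual


class NumericalErrorFromMass(InputError):
    def __init__(self, residual: float) -> None:
        super().__init__(f"segment masses do not sum to the measured mass (residual {residual:g} kg)")


def default_instrumentation() -> dict[str, float]:
    """Mass map of the wearable motion-capture hardware (kg per segment).

    Seventeen 10 g inertial units (head, sternum, pelvis and both shoulders,
    upper arms, forearms, hands, upper legs, lower legs, feet), a 150 g
    communication pack and a 70 g battery worn on the upper trunk; 0.390 kg in
    total.  Sternum and shoulder units sit on the merged upper-trunk segment.
    """
    imu = 0.010
    instr = {
        "head": imu,
        "upper_trunk": 3 * imu + 0.150 + 0.070,  # sternum + 2 shoulders + pack + battery
        "pelvis": imu,
    }
    for seg in ("upper_arm", "forearm", "hand", "upper_leg", "lower_leg", "foot"):
        for side in ("l", "r"):
            instr[f"{seg}_{side}"] = imu
    return instr


def scale_body(
    params: Mapping[str, SegmentParams],
    total_measured_mass_kg: float,
    height_m: float,
    segment_lengths_m: Mapping[str, float],
    instrumentation: Mapping[str, float] | None = None,
    gravity: float = STANDARD_GRAVITY,
) -> BodyModel:
    """Build the scaled model from anthropometry.

    ``total_measured_mass_kg`` is the mass on the scale, i.e. net body mass plus
    any worn instrumentation.  The instrumentation total is subtracted before
    the mass fractions are applied, and each component is then added back to the
    segment carrying it, so the segment masses sum exactly to the measured mass.

    ``segment_lengths_m`` must provide one entry per canonical segment name
    (``SEGMENT_NAMES``); bilateral entries may instead be given per table row.
    """
    instrumentation = dict(instrumentation or {})
    unknown = set(instrumentation) - set(SEGMENT_NAMES)
    if unknown:
        raise ConfigurationError(f"instrumentation on unknown segments: {sorted(unknown)}")
    instr_total = sum(instrumentation.values())
    net_mass = total_measured_mass_kg - instr_total
    if net_mass <= 0:
        raise InputError(
            f"net body mass must be positive (measured {total_measured_mass_kg} kg, "
            f"instrumentation {instr_total} kg)"
        )
    if height_m <= 0:
        raise InputError("height must be positive")

    segments: dict[str, ScaledSegment] = {}
    for name in SEGMENT_NAMES:
        row = table_row(name)
        if row not in params:
            raise ConfigurationError(f"anthropometric table has no row for {row!r}")
        p = params[row]
        length = segment_lengths_m.get(name, segment_lengths_m.get(row))
        if length is None:
            raise ConfigurationError(f"missing segment length for {name!r}")
        if length <= 0:
            raise InputError(f"segment length for {name!r} must be positive")
        mass = p.mass_fraction * net_mass + instrumentation.get(name, 0.0)
        inertia = segment_inertia(mass, length, p.gyration_fractions)
        com = np.array([0.0, 0.0, p.com_longitudinal_fraction * length])
        segments[name] = ScaledSegment(
            name=name,
            mass=mass,
            length=length,
            com_offset_local=com,
            inertia_com_local=inertia,
            endpoint_offsets_local={
                "proximal": np.zeros(3),
                "distal": np.array([0.0, 0.0, length]),
            },
        )

    body = BodyModel(
        segments=segments,
        total_mass=total_measured_mass_kg,
        height=height_m,
        gravity=np.array([0.0, 0.0, -abs(gravity)]),
    )
    body.mass_check()
    return body
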