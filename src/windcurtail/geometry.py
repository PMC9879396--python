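"""Site geometry and kinematic primitives.

Turbines, their rotor-swept zones (RSZ), camera towers, and the distance /
approach-speed / time-to-collision calculations that feed the curtailment
prescription.  All coordinates are local planar metres (east, north, up);
site extents are far below the scale where geodesy matters.

The RSZ is modelled as a sphere of rotor radius centred at hub height: the
rotor's yaw is unknown at decision time, so the yaw-agnostic bounding volume
is used.  The true swept disc is a subset of the sphere, which makes
distance binning conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TurbineSpec",
    "RSZModel",
    "CameraTower",
    "CoverageClass",
    "distance_to_rsz",
    "time_to_collision",
    "in_cylinder",
    "classify_coverage",
    "read_layout",
    "write_layout",
    "NEVER",
]

#: Sentinel for "target never reaches the RSZ on its current heading".
NEVER = math.inf

# Turbine dimensions of the assessed site (GE SLE 1.5 MW).
DEFAULT_HUB_HEIGHT = 65.0
DEFAULT_ROTOR_DIAMETER = 77.0
DEFAULT_DETECTION_RANGE = 1000.0
DEFAULT_COVERAGE_BUFFER = 600.0


def _as_point(p: Sequence[float], dim: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (dim,):
        raise ValueError(f"expected a {dim}-D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite coordinates: {arr!r}")
    return arr


@dataclass(frozen=True)
class TurbineSpec:
    """A turbine: ground position plus rotor dimensions.

    ``tip_height`` is derived as ``hub_height + rotor_diameter / 2`` when not
    given; if given it must agree with that sum to 1e-6 m.
    """

    turbine_id: str
    base_position: tuple[float, float]
    hub_height: float = DEFAULT_HUB_HEIGHT
    rotor_diameter: float = DEFAULT_ROTOR_DIAMETER
    tip_height: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_position", tuple(float(c) for c in self.base_position))
        _as_point(self.base_position, 2)
        if self.hub_height <= 0:
            raise ValueError(f"hub_height must be > 0, got {self.hub_height}")
        if self.rotor_diameter <= 0:
            raise ValueError(f"rotor_diameter must be > 0, got {self.rotor_diameter}")
        if self.rotor_diameter / 2 >= self.hub_height:
            raise ValueError("rotor radius must be smaller than hub height (rotor would touch ground)")
        expected_tip = self.hub_height + self.rotor_diameter / 2
        if self.tip_height is None:
            object.__setattr__(self, "tip_height", expected_tip)
        elif abs(self.tip_height - expected_tip) > 1e-6:
            raise ValueError(
                f"tip_height {self.tip_height} inconsistent with hub_height + rotor_diameter/2 = {expected_tip}"
            )

    @property
    def rotor_radius(self) -> float:
        return self.rotor_diameter / 2

    @property
    def rsz(self) -> "RSZModel":
        x, y = self.base_position
        return RSZModel(center=(x, y, self.hub_height), radius=self.rotor_radius)


@dataclass(frozen=True)
class RSZModel:
    """Spherical rotor-swept-zone model: centre at hub, radius = rotor radius."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        _as_point(self.center, 3)
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class CameraTower:
    """A detection camera tower with an effective detection range."""

    tower_id: str
    position: tuple[float, float]
    detection_range: float = DEFAULT_DETECTION_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))
        _as_point(self.position, 2)
        if self.detection_range <= 0:
            raise ValueError(f"detection_range must be > 0, got {self.detection_range}")


class CoverageClass(str, Enum):
    """How completely the cameras cover the surroundings of a turbine."""

    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


def distance_to_rsz(p: Sequence[float], rsz: RSZModel) -> float:
    """Signed Euclidean distance from ``p`` to the RSZ sphere surface.

    Negative or zero means the point is inside (or on) the RSZ.
    """
    pt = _as_point(p, 3)
    return float(np.linalg.norm(pt - np.asarray(rsz.center)) - rsz.radius)


def time_to_collision(p: Sequence[float], v: Sequence[float], rsz: RSZModel) -> float:
    """Seconds until a target at ``p`` with velocity ``v`` reaches the RSZ.

    The closing speed is the component of ``v`` along the unit vector from
    ``p`` toward the sphere centre (i.e. ``-d/dt ||p - center||``).  Returns
    0 for a point already inside the RSZ, ``NEVER`` (inf) for a target whose
    range to the centre is not shrinking.
    """
    pt = _as_point(p, 3)
    vel = _as_point(v, 3)
    d = distance_to_rsz(pt, rsz)
    if d <= 0:
        return 0.0
    r = np.asarray(rsz.center) - pt
    range_to_center = float(np.linalg.norm(r))
    if range_to_center == 0.0:
        return 0.0
    closing_speed = float(np.dot(vel, r) / range_to_center)
    if closing_speed <= 0:
        return NEVER
    return d / closing_speed


def in_cylinder(
    p: Sequence[float],
    turbine: TurbineSpec,
    radius: float,
    height_cap: float,
) -> bool:
    """True iff ``p`` lies within the vertical cylinder of ``radius`` around the
    turbine base, between ground level and ``height_cap``.  Boundaries are
    inclusive on both radius and height.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if height_cap <= 0:
        raise ValueError(f"height_cap must be > 0, got {height_cap}")
    pt = _as_point(p, 3)
    bx, by = turbine.base_position
    horiz = math.hypot(pt[0] - bx, pt[1] - by)
    return horiz <= radius and 0.0 <= pt[2] <= height_cap


def classify_coverage(
    turbine: TurbineSpec,
    cameras: Sequence[CameraTower],
    buffer: float = DEFAULT_COVERAGE_BUFFER,
    n_boundary_samples: int = 3600,
) -> CoverageClass:
    """Classify how well the camera network covers a turbine.

    ``full``    — every point of the ``buffer``-radius disc around the turbine
                  base lies inside the union of the camera detection discs;
    ``partial`` — not full, but the base itself is within range of a camera;
    ``none``    — otherwise.

    Union containment is tested by sampling the disc boundary (default 3600
    points, 0.1 degree steps) plus the centre; exact circle-union algebra is
    not warranted at this precision.
    """
    if not cameras:
        raise ValueError("at least one camera is required")
    if buffer <= 0:
        raise ValueError(f"buffer must be > 0, got {buffer}")

    base = np.asarray(turbine.base_position)
    cam_xy = np.array([c.position for c in cameras])       # (m, 2)
    cam_rng = np.array([c.detection_range for c in cameras])

    def covered(points: np.ndarray) -> bool:
        # points: (k, 2); each must be within range of >= 1 camera
        d = np.linalg.norm(points[:, None, :] - cam_xy[None, :, :], axis=2)
        return bool(np.all(np.any(d <= cam_rng[None, :], axis=1)))

    theta = np.linspace(0.0, 2 * math.pi, n_boundary_samples, endpoint=False)
    boundary = base + buffer * np.column_stack([np.cos(theta), np.sin(theta)])
    if covered(boundary) and covered(base[None, :]):
        return CoverageClass.FULL
    if covered(base[None, :]):
        return CoverageClass.PARTIAL
    return CoverageClass.NONE


# ---------------------------------------------------------------------------
# Layout file I/O

def read_layout(turbines_csv: Path | str, cameras_csv: Path | str) -> tuple[list[TurbineSpec], list[CameraTower]]:
    """Read ``turbines.csv`` and ``cameras.csv`` into domain objects."""
    tdf = pd.read_csv(turbines_csv, dtype={"turbine_id": str})
    required = {"turbine_id", "x_m", "y_m", "hub_height_m", "rotor_diameter_m"}
    if not required.issubset(tdf.columns):
        raise ValueError(f"turbines file missing columns: {sorted(required - set(tdf.columns))}")
    turbines = [
        TurbineSpec(
            turbine_id=row.turbine_id,
            base_position=(row.x_m, row.y_m),
            hub_height=row.hub_height_m,
            rotor_diameter=row.rotor_diameter_m,
        )
        for row in tdf.itertuples()
    ]
    cdf = pd.read_csv(cameras_csv, dtype={"tower_id": str})
    required = {"tower_id", "x_m", "y_m", "range_m"}
    if not required.issubset(cdf.columns):
        raise ValueError(f"cameras file missing columns: {sorted(required - set(cdf.columns))}")
    cameras = [
        CameraTower(tower_id=row.tower_id, position=(row.x_m, row.y_m), detection_range=row.range_m)
        for row in cdf.itertuples()
    ]
    return turbines, cameras


def write_layout(
    turbines: Iterable[TurbineSpec],
    cameras: Iterable[CameraTower],
    turbines_csv: Path | str,
    cameras_csv: Path | str,
) -> None:
    pd.DataFrame(
        [
            {
                "turbine_id": t.turbine_id,
                "x_m": t.base_position[0],
                "y_m": t.base_position[1],
                "hub_height_m": t.hub_height,
                "rotor_diameter_m": t.rotor_diameter,
            }
            for t in turbines
        ]
    ).to_csv(turbines_csv, index=False)
    pd.DataFrame(
        [
            {
                "tower_id": c.tower_id,
                "x_m": c.position[0],
                "y_m": c.position[1],
                "range_m": c.detection_range,
            }
            for c in cameras
        ]
    ).to_csv(cameras_csv, index=False)
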