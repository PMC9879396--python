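"""Curtailment prescription engine.

A per-record decision rule plus an order state machine.  A record triggers a
curtailment for a turbine when

    confidence > threshold  AND  ( (within the outer cylinder AND
                                    time to collision <= limit)
                                   OR within the inner cylinder )

An order opens at the first qualifying record and closes ``release_hold``
seconds after the last one; a re-trigger before the close extends the same
order, so orders of one (track, turbine) pair never overlap.

Velocity is estimated by central finite differences over adjacent records
(one-sided at track ends).  A single-record track has no velocity estimate,
so only the inner-cylinder clause can fire for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .geometry import TurbineSpec, distance_to_rsz, in_cylinder, time_to_collision
from .records import Track, TrackRecord

__all__ = [
    "PrescriptionConfig",
    "CurtailmentOrder",
    "DISTANCE_FAR",
    "DISTANCE_NEAR",
    "DISTANCE_WITHIN",
    "NEAR_LIMIT_M",
    "distance_class",
    "estimate_velocities",
    "conditions_met",
    "closest_approach",
    "run_orders",
    "read_orders",
    "write_orders",
]

DISTANCE_FAR = "far"
DISTANCE_NEAR = "near"
DISTANCE_WITHIN = "within"

#: Boundary between the "near" and "far" closest-approach classes.
NEAR_LIMIT_M = 100.0


class PrescriptionConfig(BaseModel):
    """Thresholds of the curtailment prescription.

    The confidence test is strict (``>``).  Cylinder radii are configurable
    because the deployed values are operator-defined; defaults follow the
    reference deployment: 89 % confidence, 60 s time-to-collision limit,
    outer cylinder at the 1000 m detection range, inner cylinder at 100 m,
    height cap at twice the blade-tip height, 3-minute release hold.
    """

    confidence_threshold: float = Field(default=0.89, gt=0.0, lt=1.0)
    ttc_limit_s: float = Field(default=60.0, gt=0.0)
    outer_radius_m: float = Field(default=1000.0, gt=0.0)
    inner_radius_m: float = Field(default=100.0, gt=0.0)
    height_cap_m: float = Field(default=207.0, gt=0.0)
    release_hold_s: float = Field(default=180.0, ge=0.0)

    @model_validator(mode="after")
    def _inner_below_outer(self) -> "PrescriptionConfig":
        if self.inner_radius_m >= self.outer_radius_m:
            raise ValueError("inner_radius_m must be smaller than outer_radius_m")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PrescriptionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def distance_class(closest_m: float, near_limit: float = NEAR_LIMIT_M) -> str:
    """Partition a signed closest-approach distance into within/near/far."""
    if closest_m <= 0:
        return DISTANCE_WITHIN
    if closest_m <= near_limit:
        return DISTANCE_NEAR
    return DISTANCE_FAR


@dataclass(frozen=True)
class CurtailmentOrder:
    """One (virtual) curtailment of one turbine for one track."""

    order_id: str
    turbine_id: str
    track_id: str
    start: datetime
    end: datetime
    closest_distance_m: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("order end before start")

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def distance_class(self) -> str:
        return distance_class(self.closest_distance_m)


def estimate_velocities(track: Track) -> list[np.ndarray | None]:
    """Per-record velocity estimates (m/s) by central finite differences.

    One-sided differences at the ends; ``None`` for a single-record track or
    wherever the spanning time step is zero.
    """
    n = len(track.records)
    if n == 1:
        return [None]
    pos = np.array([[r.x, r.y, r.z] for r in track.records])
    t = np.array(
        [(r.timestamp - track.records[0].timestamp).total_seconds() for r in track.records]
    )
    vels: list[np.ndarray | None] = []
    for i in range(n):
        j, k = max(i - 1, 0), min(i + 1, n - 1)
        dt = t[k] - t[j]
        vels.append((pos[k] - pos[j]) / dt if dt > 0 else None)
    return vels


def conditions_met(
    record: TrackRecord,
    velocity: np.ndarray | None,
    turbine: TurbineSpec,
    cfg: PrescriptionConfig,
) -> bool:
    """Evaluate the prescription for one record against one turbine."""
    if not record.confidence > cfg.confidence_threshold:
        return False
    p = record.position
    if in_cylinder(p, turbine, cfg.inner_radius_m, cfg.height_cap_m):
        return True
    if velocity is None:
        return False
    if not in_cylinder(p, turbine, cfg.outer_radius_m, cfg.height_cap_m):
        return False
    return time_to_collision(p, velocity, turbine.rsz) <= cfg.ttc_limit_s


def closest_approach(track: Track, turbine: TurbineSpec) -> float:
    """Minimum signed RSZ distance over the whole track (<= 0: entered)."""
    rsz = turbine.rsz
    return min(distance_to_rsz(r.position, rsz) for r in track.records)


def run_orders(
    track: Track,
    turbines: Sequence[TurbineSpec],
    cfg: PrescriptionConfig,
) -> list[CurtailmentOrder]:
    """Run the order state machine for one track against every turbine.

    Per turbine: an order opens at the first qualifying record, closes
    ``release_hold_s`` after the last qualifying record, and is extended when
    conditions re-trigger before the close.  A track near several turbines
    curtails each of them independently.  Each order carries the track's
    closest approach to that turbine.
    """
    velocities = estimate_velocities(track)
    hold = timedelta(seconds=cfg.release_hold_s)
    orders: list[CurtailmentOrder] = []
    for turbine in turbines:
        closest = None
        start = None
        last_met = None
        seq = 0
        for rec, vel in zip(track.records, velocities):
            if not conditions_met(rec, vel, turbine, cfg):
                continue
            t = rec.timestamp
            if start is None:
                start, last_met = t, t
            elif t <= last_met + hold:
                last_met = t
            else:
                if closest is None:
                    closest = closest_approach(track, turbine)
                orders.append(
                    _make_order(track, turbine, start, last_met + hold, closest, seq)
                )
                seq += 1
                start, last_met = t, t
        if start is not None:
            if closest is None:
                closest = closest_approach(track, turbine)
            orders.append(_make_order(track, turbine, start, last_met + hold, closest, seq))
    return orders


def _make_order(
    track: Track,
    turbine: TurbineSpec,
    start: datetime,
    end: datetime,
    closest: float,
    seq: int,
) -> CurtailmentOrder:
    return CurtailmentOrder(
        order_id=f"{track.track_id}:{turbine.turbine_id}:{seq}",
        turbine_id=turbine.turbine_id,
        track_id=track.track_id,
        start=start,
        end=end,
        closest_distance_m=closest,
    )


# ---------------------------------------------------------------------------
# Orders file I/O

_ORDER_COLUMNS = [
    "order_id",
    "turbine_id",
    "track_id",
    "start",
    "end",
    "duration_h",
    "closest_m",
    "distance_class",
]


def write_orders(orders: Iterable[CurtailmentOrder], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "order_id": o.order_id,
                "turbine_id": o.turbine_id,
                "track_id": o.track_id,
                "start": o.start.isoformat(),
                "end": o.end.isoformat(),
                "duration_h": o.duration_h,
                "closest_m": o.closest_distance_m,
                "distance_class": o.distance_class,
            }
            for o in orders
        ],
        columns=_ORDER_COLUMNS,
    ).to_csv(path, index=False)


def read_orders(path: Path | str) -> list[CurtailmentOrder]:
    df = pd.read_csv(path, dtype={"order_id": str, "turbine_id": str, "track_id": str})
    return [
        CurtailmentOrder(
            order_id=row.order_id,
            turbine_id=row.turbine_id,
            track_id=row.track_id,
            start=datetime.fromisoformat(row.start),
            end=datetime.fromisoformat(row.end),
            closest_distance_m=float(row.closest_m),
        )
        for row in df.itertuples()
    ]
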