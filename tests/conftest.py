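from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from windcurtail.geometry import CameraTower, TurbineSpec
from windcurtail.identification import TimePeriod
from windcurtail.records import EAGLE, NON_EAGLE, Track, TrackRecord

T0 = datetime(2021, 1, 10, 12, 0, 0, tzinfo=timezone.utc)


@pytest.fixture
def turbine() -> TurbineSpec:
    return TurbineSpec("t-1", (0.0, 0.0))


@pytest.fixture
def camera() -> CameraTower:
    return CameraTower("cam-1", (0.0, 0.0))


@pytest.fixture
def periods() -> list[TimePeriod]:
    return [
        TimePeriod("p1", "2021-01-01", "2021-02-09"),
        TimePeriod("p2", "2021-02-10", "2021-03-21"),
    ]


def make_record(
    track_id: str = "trk-1",
    t: datetime | float = T0,
    x: float = 0.0,
    y: float = 0.0,
    z: float = 65.0,
    label: str = NON_EAGLE,
    confidence: float = 0.5,
    has_image: bool = True,
    target_index: int = 0,
    tower_id: str = "cam-1",
) -> TrackRecord:
    if not isinstance(t, datetime):
        t = T0 + timedelta(seconds=float(t))
    return TrackRecord(
        track_id=track_id,
        tower_id=tower_id,
        timestamp=t,
        x=x,
        y=y,
        z=z,
        system_label=label,
        confidence=confidence,
        has_image=has_image,
        target_index=target_index,
    )


def make_track(records: list[TrackRecord], determination: str | None = None) -> Track:
    return Track(
        track_id=records[0].track_id,
        tower_id=records[0].tower_id,
        records=sorted(records, key=lambda r: r.timestamp),
        determination=determination,
    )


def straight_track(
    track_id: str,
    start_xyz: tuple[float, float, float],
    velocity: tuple[float, float, float],
    n: int,
    confidence: float = 1.0,
    label: str = EAGLE,
    t0: datetime = T0,
    dt: float = 1.0,
) -> Track:
    """Constant-velocity track sampled at ``dt`` seconds."""
    recs = []
    for i in range(n):
        recs.append(
            make_record(
                track_id=track_id,
                t=t0 + timedelta(seconds=i * dt),
                x=start_xyz[0] + velocity[0] * i * dt,
                y=start_xyz[1] + velocity[1] * i * dt,
                z=start_xyz[2] + velocity[2] * i * dt,
                label=label,
                confidence=confidence,
            )
        )
    return make_track(recs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
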