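"""Synthetic input bundles: flight tracks, classifier output, reviewer labels
and site layout, so every pipeline stage is testable without field data.

Flight paths are correlated random walks at 1 Hz inside camera detection
range; a configurable share of tracks is forced onto straight transits
through a rotor-swept zone so every closest-approach class occurs.  System
labels flip the true species with per-period false-negative / false-positive
probabilities, applied per record (the evaluation computes rates over
records).  Everything is driven by one seeded generator: a fixed seed gives
byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .geometry import CameraTower, TurbineSpec, write_layout
from .identification import TimePeriod, dump_periods
from .records import (
    EAGLE,
    NON_EAGLE,
    ReviewSet,
    TrackRecord,
    write_archive,
    write_reviews,
)

__all__ = [
    "SimConfig",
    "SimTrack",
    "Bundle",
    "default_layout",
    "default_periods",
    "simulate_tracks",
    "simulate_classifier",
    "simulate_reviews",
    "generate_bundle",
    "write_bundle",
]

#: Default eagle share, from the ~140:1 raven-to-eagle abundance ratio
#: reported for the study region.
DEFAULT_EAGLE_FRACTION = 1.0 / 141.0


class SimConfig(BaseModel):
    """Knobs of the synthetic-bundle generator."""

    seed: int = 0
    n_tracks: int = Field(default=200, gt=0)
    eagle_fraction: float = Field(default=DEFAULT_EAGLE_FRACTION, ge=0.0, le=1.0)
    track_duration_s: tuple[int, int] = (10, 600)
    speed_range_ms: tuple[float, float] = (5.0, 20.0)
    turn_kappa: float = Field(default=8.0, gt=0.0)
    altitude_range_m: tuple[float, float] = (30.0, 160.0)
    p_no_image: float = Field(default=0.02, ge=0.0, le=1.0)
    p_multi_target: float = Field(default=0.005, ge=0.0, le=1.0)
    forced_transit_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    reviewer_error: float = Field(default=0.02, ge=0.0, lt=0.5)
    #: Misclassification probabilities per period name (or one value for all).
    fn_rate: float | dict[str, float] = 0.2
    fp_rate: float | dict[str, float] = 0.15
    #: Share of eagle-labelled records whose confidence exceeds 0.89.
    high_conf_share: float = Field(default=0.85, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ranges(self) -> "SimConfig":
        for name in ("track_duration_s", "speed_range_ms", "altitude_range_m"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        return self

    def rate_for(self, which: str, period: str) -> float:
        value = getattr(self, which)
        if isinstance(value, dict):
            if period not in value:
                raise KeyError(f"{which} has no entry for period {period!r}")
            return value[period]
        return value


@dataclass
class SimTrack:
    """A simulated flight path before classification."""

    track_id: str
    tower_id: str
    period: str
    timestamps: list[datetime]
    positions: np.ndarray  # (n, 3)
    true_species: str
    has_image: bool


@dataclass
class Bundle:
    """A complete synthetic input set."""

    records: list[TrackRecord]
    reviews: list[ReviewSet]
    turbines: list[TurbineSpec]
    cameras: list[CameraTower]
    periods: list[TimePeriod]
    truth: dict[str, str]  # track_id -> true species
    config: SimConfig


def default_layout() -> tuple[list[TurbineSpec], list[CameraTower]]:
    """A small two-camera site with fully and partially covered turbines."""
    cameras = [
        CameraTower("cam-1", (0.0, 0.0)),
        CameraTower("cam-2", (1500.0, 0.0)),
    ]
    turbines = [
        TurbineSpec("t-1", (400.0, 0.0)),
        TurbineSpec("t-2", (750.0, 0.0)),
        TurbineSpec("t-3", (0.0, 900.0)),
        TurbineSpec("t-4", (-800.0, -500.0)),
    ]
    return turbines, cameras


def default_periods() -> list[TimePeriod]:
    """Five contiguous 10-week study periods."""
    out = []
    start = datetime(2021, 1, 4).date()
    for i in range(5):
        end = start + timedelta(days=69)
        out.append(TimePeriod(name=f"period-{i + 1}", start=start, end=end))
        start = end + timedelta(days=1)
    return out


def _random_day(period: TimePeriod, rng: np.random.Generator):
    days = list(period.dates())
    return days[int(rng.integers(len(days)))]


def _walk_positions(
    n: int,
    origin: np.ndarray,
    speed: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated random walk: von Mises heading increments, altitude jitter."""
    heading = rng.uniform(0, 2 * math.pi)
    turns = rng.vonmises(0.0, cfg.turn_kappa, size=n - 1) if n > 1 else np.empty(0)
    headings = heading + np.concatenate([[0.0], np.cumsum(turns)])
    steps = speed * np.column_stack([np.cos(headings), np.sin(headings)])
    xy = origin[:2] + np.concatenate([[[0.0, 0.0]], np.cumsum(steps[:-1], axis=0)]) if n > 1 else origin[None, :2]
    lo, hi = cfg.altitude_range_m
    dz = np.concatenate([[0.0], rng.normal(0.0, 2.0, size=n - 1)])
    z = np.clip(origin[2] + np.cumsum(dz), lo, hi)
    return np.column_stack([xy, z])


def _transit_positions(
    n: int,
    turbine: TurbineSpec,
    speed: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Straight constant-velocity transit aimed at (or near) the RSZ centre."""
    cx, cy = turbine.base_position
    bearing = rng.uniform(0, 2 * math.pi)
    start_dist = rng.uniform(500.0, 900.0)
    start = np.array([cx + start_dist * math.cos(bearing), cy + start_dist * math.sin(bearing)])
    # miss distance 0..2 rotor radii: some transits enter, some pass near
    miss = rng.uniform(0.0, 2.0 * turbine.rotor_radius)
    perp = np.array([-math.sin(bearing), math.cos(bearing)])
    aim = np.array([cx, cy]) + miss * perp
    direction = aim - start
    direction /= np.linalg.norm(direction)
    t = np.arange(n)[:, None] * speed
    xy = start[None, :] + t * direction[None, :]
    z0 = turbine.hub_height + rng.uniform(-0.5, 0.5) * turbine.rotor_radius
    lo, hi = cfg.altitude_range_m
    z = np.full(n, float(np.clip(z0, lo, hi)))
    return np.column_stack([xy, z])


def simulate_tracks(
    cfg: SimConfig,
    turbines: Sequence[TurbineSpec],
    cameras: Sequence[CameraTower],
    periods: Sequence[TimePeriod],
    rng: np.random.Generator,
) -> list[SimTrack]:
    """Generate flight tracks with true species labels."""
    tracks = []
    weights = np.array([p.n_days for p in periods], dtype=float)
    weights /= weights.sum()
    for i in range(cfg.n_tracks):
        species = EAGLE if rng.random() < cfg.eagle_fraction else NON_EAGLE
        camera = cameras[int(rng.integers(len(cameras)))]
        lo, hi = cfg.track_duration_s
        n = int(rng.integers(lo, hi + 1))
        speed = rng.uniform(*cfg.speed_range_ms)
        if turbines and rng.random() < cfg.forced_transit_fraction:
            turbine = turbines[int(rng.integers(len(turbines)))]
            positions = _transit_positions(n, turbine, speed, cfg, rng)
        else:
            radius = camera.detection_range * math.sqrt(rng.random())
            angle = rng.uniform(0, 2 * math.pi)
            origin = np.array(
                [
                    camera.position[0] + radius * math.cos(angle),
                    camera.position[1] + radius * math.sin(angle),
                    rng.uniform(*cfg.altitude_range_m),
                ]
            )
            positions = _walk_positions(n, origin, speed, cfg, rng)
        period = periods[int(rng.choice(len(periods), p=weights))]
        day = _random_day(period, rng)
        start_s = int(rng.integers(0, max(86400 - n, 1)))
        t0 = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(seconds=start_s)
        timestamps = [t0 + timedelta(seconds=k) for k in range(n)]
        tracks.append(
            SimTrack(
                track_id=f"trk-{i:06d}",
                tower_id=camera.tower_id,
                period=period.name,
                timestamps=timestamps,
                positions=positions,
                true_species=species,
                has_image=bool(rng.random() >= cfg.p_no_image),
            )
        )
    return tracks


def _confidence(label: str, cfg: SimConfig, rng: np.random.Generator) -> float:
    if label == EAGLE:
        if rng.random() < cfg.high_conf_share:
            return 0.89 + 0.11 * rng.beta(2.0, 2.0)
        return 0.89 * rng.beta(6.0, 2.0)
    return float(rng.beta(2.0, 6.0))


def simulate_classifier(
    tracks: Sequence[SimTrack],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[TrackRecord]:
    """Attach per-record system labels and confidences; emit archive records.

    Each record of a true eagle is labelled non-eagle with the period's FN
    probability; each record of a true non-eagle is labelled eagle with the
    period's FP probability.  A small share of records carries a second
    target (index 1), emulating two birds in one image.
    """
    records = []
    for track in tracks:
        flip_p = cfg.rate_for("fn_rate" if track.true_species == EAGLE else "fp_rate", track.period)
        flips = rng.random(len(track.timestamps)) < flip_p
        for ts, pos, flipped in zip(track.timestamps, track.positions, flips):
            if track.true_species == EAGLE:
                label = NON_EAGLE if flipped else EAGLE
            else:
                label = EAGLE if flipped else NON_EAGLE
            records.append(
                TrackRecord(
                    track_id=track.track_id,
                    tower_id=track.tower_id,
                    timestamp=ts,
                    x=float(pos[0]),
                    y=float(pos[1]),
                    z=float(pos[2]),
                    system_label=label,
                    confidence=_confidence(label, cfg, rng),
                    has_image=track.has_image,
                    target_index=0,
                )
            )
            if rng.random() < cfg.p_multi_target:
                extra_label = EAGLE if rng.random() < 0.5 else NON_EAGLE
                records.append(
                    TrackRecord(
                        track_id=track.track_id,
                        tower_id=track.tower_id,
                        timestamp=ts,
                        x=float(pos[0] + rng.normal(0, 5)),
                        y=float(pos[1] + rng.normal(0, 5)),
                        z=float(pos[2]),
                        system_label=extra_label,
                        confidence=_confidence(extra_label, cfg, rng),
                        has_image=track.has_image,
                        target_index=1,
                    )
                )
    return records


def simulate_reviews(
    truth: Mapping[str, str],
    reviewer_error: float,
    rng: np.random.Generator,
) -> list[ReviewSet]:
    """Two independent noisy reviewer labels per track, a third on splits."""
    if not 0 <= reviewer_error < 0.5:
        raise ValueError("reviewer_error must be in [0, 0.5)")

    def noisy(true_label: str) -> str:
        if rng.random() < reviewer_error:
            return NON_EAGLE if true_label == EAGLE else EAGLE
        return true_label

    reviews = []
    for track_id, species in truth.items():
        r1, r2 = noisy(species), noisy(species)
        r3 = noisy(species) if r1 != r2 else None
        reviews.append(ReviewSet(track_id=track_id, reviewer_1=r1, reviewer_2=r2, reviewer_3=r3))
    return reviews


def generate_bundle(
    cfg: SimConfig,
    turbines: Sequence[TurbineSpec] | None = None,
    cameras: Sequence[CameraTower] | None = None,
    periods: Sequence[TimePeriod] | None = None,
) -> Bundle:
    """Generate a full input bundle from one seeded generator."""
    if turbines is None or cameras is None:
        default_t, default_c = default_layout()
        turbines = turbines if turbines is not None else default_t
        cameras = cameras if cameras is not None else default_c
    periods = list(periods) if periods is not None else default_periods()
    rng = np.random.default_rng(cfg.seed)
    tracks = simulate_tracks(cfg, turbines, cameras, periods, rng)
    records = simulate_classifier(tracks, cfg, rng)
    truth = {t.track_id: t.true_species for t in tracks}
    reviewable = {t.track_id: t.true_species for t in tracks if t.has_image}
    reviews = simulate_reviews(reviewable, cfg.reviewer_error, rng)
    return Bundle(
        records=records,
        reviews=reviews,
        turbines=list(turbines),
        cameras=list(cameras),
        periods=periods,
        truth=truth,
        config=cfg,
    )


def write_bundle(bundle: Bundle, out_dir: Path | str) -> None:
    """Write a bundle as records.csv, reviews.csv, turbines.csv, cameras.csv,
    periods.yaml and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_archive(bundle.records, out / "records.csv")
    write_reviews(bundle.reviews, out / "reviews.csv")
    write_layout(bundle.turbines, bundle.cameras, out / "turbines.csv", out / "cameras.csv")
    dump_periods(bundle.periods, out / "periods.yaml")
    pd.DataFrame(
        [{"track_id": k, "species": v} for k, v in bundle.truth.items()]
    ).to_csv(out / "truth.csv", index=False)
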