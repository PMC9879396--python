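"""Archive-record ingestion, track assembly, exclusion filters and review
adjudication.

The archive is a ~1 Hz stream of per-target observations grouped into tracks.
Before any rate is computed the stream passes three steps:

1. multi-target filter — when one timestamp of a track carries more than one
   unique target, only the first target (index 0) is retained;
2. no-image filter — tracks whose records all lack an image cannot be
   reviewed; they are set aside with determination ``no-image`` and tallied,
   but excluded from every rate denominator;
3. adjudication — two independent reviewer labels per track, a third reviewer
   breaking disagreements.

All filters conserve records: kept + dropped + no-image equals the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EAGLE",
    "NON_EAGLE",
    "NO_IMAGE",
    "LABELS",
    "TrackRecord",
    "Track",
    "ReviewSet",
    "ArchiveValidationError",
    "read_archive",
    "write_archive",
    "assemble_tracks",
    "filter_multi_target",
    "filter_no_image_tracks",
    "adjudicate",
    "read_reviews",
    "write_reviews",
    "apply_determinations",
    "build_determined_tracks",
]

EAGLE = "eagle"
NON_EAGLE = "non-eagle"
NO_IMAGE = "no-image"
LABELS = (EAGLE, NON_EAGLE)


class ArchiveValidationError(ValueError):
    """Raised when an archive row fails validation; names the offending row."""


@dataclass(frozen=True)
class TrackRecord:
    """One per-second observation of one target."""

    track_id: str
    tower_id: str
    timestamp: datetime
    x: float
    y: float
    z: float
    system_label: str
    confidence: float
    has_image: bool = True
    target_index: int = 0

    def __post_init__(self) -> None:
        if self.system_label not in LABELS:
            raise ValueError(f"unknown system label {self.system_label!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.target_index < 0:
            raise ValueError(f"target_index must be >= 0, got {self.target_index}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track:
    """Ordered records sharing a track ID, plus the adjudicated determination."""

    track_id: str
    tower_id: str
    records: list[TrackRecord]
    determination: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a track needs at least one record")
        if any(r.track_id != self.track_id for r in self.records):
            raise ValueError("all records of a track must share its track_id")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_any_image(self) -> bool:
        return any(r.has_image for r in self.records)


@dataclass(frozen=True)
class ReviewSet:
    """Two primary reviewer labels for a track; a third iff they disagree."""

    track_id: str
    reviewer_1: str
    reviewer_2: str
    reviewer_3: str | None = None

    def __post_init__(self) -> None:
        for label in (self.reviewer_1, self.reviewer_2):
            if label not in LABELS:
                raise ValueError(f"unknown reviewer label {label!r}")
        split = self.reviewer_1 != self.reviewer_2
        if split and self.reviewer_3 is None:
            raise ValueError(f"track {self.track_id}: reviewers disagree but no tiebreaker given")
        if not split and self.reviewer_3 is not None:
            raise ValueError(f"track {self.track_id}: tiebreaker given although reviewers agree")
        if self.reviewer_3 is not None and self.reviewer_3 not in LABELS:
            raise ValueError(f"unknown reviewer label {self.reviewer_3!r}")


def adjudicate(review: ReviewSet) -> str:
    """Final determination: unanimous label, else the tiebreaker's label."""
    if review.reviewer_1 == review.reviewer_2:
        return review.reviewer_1
    assert review.reviewer_3 is not None  # enforced by ReviewSet invariant
    return review.reviewer_3


# ---------------------------------------------------------------------------
# Archive I/O

_ARCHIVE_COLUMNS = [
    "track_id",
    "tower_id",
    "timestamp",
    "x_m",
    "y_m",
    "z_m",
    "system_label",
    "confidence",
    "has_image",
    "target_index",
]


def read_archive(path: Path | str) -> list[TrackRecord]:
    """Parse ``records.csv`` into TrackRecords, preserving row order.

    Any malformed value raises :class:`ArchiveValidationError` naming the
    1-based data row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ARCHIVE_COLUMNS if c not in df.columns]
    if missing:
        raise ArchiveValidationError(f"archive missing columns: {missing}")

    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ArchiveValidationError(f"row {bad[0] + 1}: malformed timestamp {df['timestamp'].iloc[bad[0]]!r}")

    numeric = {}
    for col in ("x_m", "y_m", "z_m", "confidence"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            raise ArchiveValidationError(f"row {bad[0] + 1}: malformed number in {col}: {df[col].iloc[bad[0]]!r}")
        numeric[col] = values.to_numpy()

    bad = np.flatnonzero((numeric["confidence"] < 0) | (numeric["confidence"] > 1))
    if bad.size:
        raise ArchiveValidationError(f"row {bad[0] + 1}: confidence {numeric['confidence'][bad[0]]} outside [0, 1]")

    labels = df["system_label"].str.strip().str.lower()
    bad = np.flatnonzero(~labels.isin(LABELS).to_numpy())
    if bad.size:
        raise ArchiveValidationError(f"row {bad[0] + 1}: unknown system label {df['system_label'].iloc[bad[0]]!r}")

    flags = df["has_image"].str.strip().str.lower()
    bad = np.flatnonzero(~flags.isin(["true", "false", "1", "0"]).to_numpy())
    if bad.size:
        raise ArchiveValidationError(f"row {bad[0] + 1}: bad has_image flag {df['has_image'].iloc[bad[0]]!r}")

    tindex = pd.to_numeric(df["target_index"], errors="coerce")
    bad = np.flatnonzero(tindex.isna().to_numpy() | (tindex < 0).to_numpy())
    if bad.size:
        raise ArchiveValidationError(f"row {bad[0] + 1}: bad target_index {df['target_index'].iloc[bad[0]]!r}")

    records = []
    for i in range(len(df)):
        records.append(
            TrackRecord(
                track_id=df["track_id"].iloc[i],
                tower_id=df["tower_id"].iloc[i],
                timestamp=ts.iloc[i].to_pydatetime(),
                x=float(numeric["x_m"][i]),
                y=float(numeric["y_m"][i]),
                z=float(numeric["z_m"][i]),
                system_label=labels.iloc[i],
                confidence=float(numeric["confidence"][i]),
                has_image=flags.iloc[i] in ("true", "1"),
                target_index=int(tindex.iloc[i]),
            )
        )
    return records


def write_archive(records: Iterable[TrackRecord], path: Path | str) -> None:
    df = pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "tower_id": r.tower_id,
                "timestamp": r.timestamp.astimezone(timezone.utc).isoformat().replace("+00:00", "Z"),
                "x_m": r.x,
                "y_m": r.y,
                "z_m": r.z,
                "system_label": r.system_label,
                "confidence": r.confidence,
                "has_image": r.has_image,
                "target_index": r.target_index,
            }
            for r in records
        ],
        columns=_ARCHIVE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_reviews(path: Path | str) -> list[ReviewSet]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"track_id", "reviewer_1", "reviewer_2", "reviewer_3"}
    if not required.issubset(df.columns):
        raise ArchiveValidationError(f"reviews file missing columns: {sorted(required - set(df.columns))}")
    reviews = []
    for i, row in enumerate(df.itertuples(), start=1):
        r3 = row.reviewer_3.strip() or None
        try:
            reviews.append(
                ReviewSet(
                    track_id=row.track_id,
                    reviewer_1=row.reviewer_1.strip().lower(),
                    reviewer_2=row.reviewer_2.strip().lower(),
                    reviewer_3=r3.lower() if r3 else None,
                )
            )
        except ValueError as exc:
            raise ArchiveValidationError(f"row {i}: {exc}") from exc
    return reviews


def write_reviews(reviews: Iterable[ReviewSet], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "reviewer_1": r.reviewer_1,
                "reviewer_2": r.reviewer_2,
                "reviewer_3": r.reviewer_3 or "",
            }
            for r in reviews
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters and assembly

def filter_multi_target(records: Sequence[TrackRecord]) -> list[TrackRecord]:
    """Keep only the first target (index 0) wherever one track timestamp
    carries more than one unique target; single-target rows pass untouched.

    Idempotent; never fabricates records.
    """
    n_targets: dict[tuple[str, datetime], set[int]] = {}
    for r in records:
        n_targets.setdefault((r.track_id, r.timestamp), set()).add(r.target_index)
    kept = [
        r
        for r in records
        if len(n_targets[(r.track_id, r.timestamp)]) == 1 or r.target_index == 0
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("multi-target filter dropped %d of %d records", dropped, len(records))
    return kept


def assemble_tracks(records: Sequence[TrackRecord]) -> list[Track]:
    """Group records into tracks by track_id (first-seen order), sorting each
    track's records by timestamp."""
    groups: dict[str, list[TrackRecord]] = {}
    for r in records:
        groups.setdefault(r.track_id, []).append(r)
    tracks = []
    for track_id, recs in groups.items():
        towers = {r.tower_id for r in recs}
        if len(towers) > 1:
            raise ArchiveValidationError(f"track {track_id} spans multiple towers: {sorted(towers)}")
        recs = sorted(recs, key=lambda r: r.timestamp)
        tracks.append(Track(track_id=track_id, tower_id=recs[0].tower_id, records=recs))
    return tracks


def filter_no_image_tracks(tracks: Sequence[Track]) -> tuple[list[Track], list[Track]]:
    """Split tracks into (reviewable, image-less).

    Image-less tracks (no record has an image) are given determination
    ``no-image``; they are kept for bookkeeping but must not enter any rate
    denominator.
    """
    kept, no_image = [], []
    for t in tracks:
        if t.has_any_image:
            kept.append(t)
        else:
            no_image.append(replace_determination(t, NO_IMAGE))
    if no_image:
        logger.info(
            "no-image filter set aside %d tracks (%d records)",
            len(no_image),
            sum(len(t) for t in no_image),
        )
    return kept, no_image


def replace_determination(track: Track, determination: str) -> Track:
    return Track(
        track_id=track.track_id,
        tower_id=track.tower_id,
        records=track.records,
        determination=determination,
    )


def apply_determinations(tracks: Sequence[Track], reviews: Mapping[str, ReviewSet]) -> list[Track]:
    """Attach adjudicated determinations to reviewable tracks."""
    out = []
    for t in tracks:
        if t.track_id not in reviews:
            raise KeyError(f"no review for track {t.track_id}")
        out.append(replace_determination(t, adjudicate(reviews[t.track_id])))
    return out


def build_determined_tracks(
    records: Sequence[TrackRecord],
    reviews: Sequence[ReviewSet],
) -> list[Track]:
    """Full preprocessing pipeline: multi-target filter, track assembly,
    no-image split, adjudication.  Returns every track (reviewable tracks
    carry their adjudicated label, image-less ones ``no-image``)."""
    filtered = filter_multi_target(records)
    tracks = assemble_tracks(filtered)
    kept, no_image = filter_no_image_tracks(tracks)
    review_map = {r.track_id: r for r in reviews}
    determined = apply_determinations(kept, review_map)
    return determined + no_image
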