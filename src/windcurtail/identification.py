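"""Identification accuracy: confusion counts and error rates, stratified by
time period (and optionally camera tower).

Rates follow the study design exactly:

* accuracy      = correct identifications / all image-bearing records;
* false-negative rate = eagle records the system called non-eagle / all
  records determined to be eagles;
* false-positive rate = non-eagle records the system called eagle / all
  records determined to be non-eagles.

The FN and FP rates are computed on disjoint denominators and do not sum
to one.  Image-less records are tallied in dedicated cells but excluded
from every denominator.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .records import EAGLE, NO_IMAGE, NON_EAGLE, Track

logger = logging.getLogger(__name__)

__all__ = [
    "TimePeriod",
    "ConfusionCounts",
    "UndefinedRateError",
    "build_confusion",
    "accuracy_rate",
    "false_negative_rate",
    "false_positive_rate",
    "cross_period_summary",
    "load_periods",
    "dump_periods",
    "counts_to_frame",
    "frame_to_counts",
    "read_counts_csv",
    "write_counts_csv",
]


class UndefinedRateError(ValueError):
    """A rate was requested with a zero denominator."""


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclass(frozen=True)
class TimePeriod:
    """A named, inclusive date interval with optional excluded sub-ranges."""

    name: str
    start: date
    end: date
    excluded: tuple[tuple[date, date], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        object.__setattr__(
            self, "excluded", tuple((_as_date(a), _as_date(b)) for a, b in self.excluded)
        )
        if self.start > self.end:
            raise ValueError(f"period {self.name}: start {self.start} after end {self.end}")
        for a, b in self.excluded:
            if a > b:
                raise ValueError(f"period {self.name}: excluded range {a}..{b} reversed")
            if a < self.start or b > self.end:
                raise ValueError(f"period {self.name}: excluded range {a}..{b} outside period")

    def contains(self, d: date) -> bool:
        if not self.start <= d <= self.end:
            return False
        return not any(a <= d <= b for a, b in self.excluded)

    @property
    def n_days(self) -> int:
        """Inclusive day count minus excluded days."""
        total = (self.end - self.start).days + 1
        excluded = sum((b - a).days + 1 for a, b in self.excluded)
        return total - excluded

    def dates(self) -> Iterable[date]:
        d = self.start
        while d <= self.end:
            if self.contains(d):
                yield d
            d += timedelta(days=1)


def _check_non_overlapping(periods: Sequence[TimePeriod]) -> None:
    for i, p in enumerate(periods):
        for q in periods[i + 1 :]:
            lo, hi = max(p.start, q.start), min(p.end, q.end)
            d = lo
            while d <= hi:
                if p.contains(d) and q.contains(d):
                    raise ValueError(f"periods {p.name!r} and {q.name!r} overlap on {d}")
                d += timedelta(days=1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Record counts of one (period [, tower]) stratum.

    Cell naming is determination first, system identification second:
    ``noneagle_as_eagle`` counts false positives, ``eagle_as_noneagle``
    false negatives.  Counts are additive across strata.
    """

    eagle_correct: int = 0
    eagle_as_noneagle: int = 0
    noneagle_as_eagle: int = 0
    noneagle_correct: int = 0
    noimage_as_eagle: int = 0
    noimage_as_noneagle: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            **{
                name: getattr(self, name) + getattr(other, name)
                for name in self.__dataclass_fields__
            }
        )

    @property
    def n_eagle(self) -> int:
        return self.eagle_correct + self.eagle_as_noneagle

    @property
    def n_noneagle(self) -> int:
        return self.noneagle_as_eagle + self.noneagle_correct

    @property
    def n_noimage(self) -> int:
        return self.noimage_as_eagle + self.noimage_as_noneagle

    @property
    def n_analyzed(self) -> int:
        """Image-bearing records — the accuracy denominator."""
        return self.n_eagle + self.n_noneagle

    @property
    def n_total(self) -> int:
        return self.n_analyzed + self.n_noimage

    @property
    def n_system_eagle(self) -> int:
        return self.eagle_correct + self.noneagle_as_eagle + self.noimage_as_eagle

    @property
    def n_system_noneagle(self) -> int:
        return self.eagle_as_noneagle + self.noneagle_correct + self.noimage_as_noneagle


def build_confusion(
    tracks: Sequence[Track],
    periods: Sequence[TimePeriod],
    group_by_tower: bool = False,
) -> dict:
    """Tally every record of every determined track into one confusion cell
    of one stratum.

    Strata are keyed by period name, or ``(period name, tower_id)`` when
    ``group_by_tower``.  Records whose date falls in no period (gaps between
    periods, excluded dates) are dropped and counted in the log.  Overlapping
    periods are an error.
    """
    _check_non_overlapping(periods)
    cells = {
        (EAGLE, EAGLE): "eagle_correct",
        (EAGLE, NON_EAGLE): "eagle_as_noneagle",
        (NON_EAGLE, EAGLE): "noneagle_as_eagle",
        (NON_EAGLE, NON_EAGLE): "noneagle_correct",
        (NO_IMAGE, EAGLE): "noimage_as_eagle",
        (NO_IMAGE, NON_EAGLE): "noimage_as_noneagle",
    }
    tallies: dict = {}
    n_dropped = 0
    for track in tracks:
        if track.determination is None:
            raise ValueError(f"track {track.track_id} has no determination")
        for rec in track.records:
            d = rec.timestamp.date()
            period = next((p for p in periods if p.contains(d)), None)
            if period is None:
                n_dropped += 1
                continue
            key = (period.name, track.tower_id) if group_by_tower else period.name
            stratum = tallies.setdefault(key, dict.fromkeys(cells.values(), 0))
            stratum[cells[(track.determination, rec.system_label)]] += 1
    if n_dropped:
        logger.info("build_confusion dropped %d records outside all periods", n_dropped)
    return {key: ConfusionCounts(**stratum) for key, stratum in tallies.items()}


def accuracy_rate(c: ConfusionCounts) -> float:
    """Correct identifications over all image-bearing records."""
    if c.n_analyzed == 0:
        raise UndefinedRateError("no image-bearing records: accuracy undefined")
    return (c.eagle_correct + c.noneagle_correct) / c.n_analyzed


def false_negative_rate(c: ConfusionCounts) -> float:
    """Eagles called non-eagle, over all eagle-determined records."""
    if c.n_eagle == 0:
        raise UndefinedRateError("no eagle-determined records: FN rate undefined")
    return c.eagle_as_noneagle / c.n_eagle


def false_positive_rate(c: ConfusionCounts) -> float:
    """Non-eagles called eagle, over all non-eagle-determined records."""
    if c.n_noneagle == 0:
        raise UndefinedRateError("no non-eagle-determined records: FP rate undefined")
    return c.noneagle_as_eagle / c.n_noneagle


def cross_period_summary(per_period: Mapping[str, ConfusionCounts]) -> dict[str, tuple[float, float]]:
    """Unweighted mean and sample (n-1) standard deviation of the per-period
    accuracy, FN and FP rates.  Needs at least two periods."""
    if len(per_period) < 2:
        raise UndefinedRateError("cross-period sd needs at least two periods")
    out = {}
    for name, fn in (
        ("accuracy", accuracy_rate),
        ("false_negative_rate", false_negative_rate),
        ("false_positive_rate", false_positive_rate),
    ):
        rates = [fn(c) for c in per_period.values()]
        out[name] = (statistics.mean(rates), statistics.stdev(rates))
    return out


# ---------------------------------------------------------------------------
# Period and counts-table I/O

def load_periods(path: Path | str) -> list[TimePeriod]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    periods = [
        TimePeriod(
            name=item["name"],
            start=item["start"],
            end=item["end"],
            excluded=tuple((a, b) for a, b in item.get("excluded", [])),
        )
        for item in raw
    ]
    _check_non_overlapping(periods)
    return periods


def dump_periods(periods: Sequence[TimePeriod], path: Path | str) -> None:
    raw = [
        {
            "name": p.name,
            "start": p.start.isoformat(),
            "end": p.end.isoformat(),
            "excluded": [[a.isoformat(), b.isoformat()] for a, b in p.excluded],
        }
        for p in periods
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


_DET_ROWS = {
    EAGLE: ("eagle_correct", "eagle_as_noneagle"),
    NON_EAGLE: ("noneagle_as_eagle", "noneagle_correct"),
    NO_IMAGE: ("noimage_as_eagle", "noimage_as_noneagle"),
}


def counts_to_frame(per_period: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Long-form counts table: one row per (period, determination), with the
    record total and the split by system identification."""
    rows = []
    for period, c in per_period.items():
        for det, (eagle_cell, noneagle_cell) in _DET_ROWS.items():
            as_eagle = getattr(c, eagle_cell)
            as_noneagle = getattr(c, noneagle_cell)
            rows.append(
                {
                    "period": period,
                    "determination": det,
                    "n_records": as_eagle + as_noneagle,
                    "id_eagle": as_eagle,
                    "id_noneagle": as_noneagle,
                }
            )
    return pd.DataFrame(rows)


def frame_to_counts(df: pd.DataFrame) -> dict[str, ConfusionCounts]:
    per_period: dict[str, ConfusionCounts] = {}
    for period, group in df.groupby("period", sort=False):
        kwargs = dict.fromkeys(
            (cell for cells in _DET_ROWS.values() for cell in cells), 0
        )
        for row in group.itertuples():
            eagle_cell, noneagle_cell = _DET_ROWS[row.determination]
            kwargs[eagle_cell] = int(row.id_eagle)
            kwargs[noneagle_cell] = int(row.id_noneagle)
            if int(row.n_records) != int(row.id_eagle) + int(row.id_noneagle):
                raise ValueError(
                    f"period {period}, {row.determination}: n_records does not equal the row sum"
                )
        per_period[str(period)] = ConfusionCounts(**kwargs)
    return per_period


def read_counts_csv(path: Path | str) -> dict[str, ConfusionCounts]:
    return frame_to_counts(pd.read_csv(path))


def write_counts_csv(per_period: Mapping[str, ConfusionCounts], path: Path | str) -> None:
    counts_to_frame(per_period).to_csv(path, index=False)
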