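"""Bundled reference dataset from a year-long two-tower field deployment.

Ships the published per-period identification counts, curtailment-order
counts by distance class, order-duration totals, and the five study-period
definitions, so the headline analyses are reproducible offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .identification import ConfusionCounts, TimePeriod, load_periods, read_counts_csv

__all__ = [
    "load_identification_counts",
    "load_order_counts",
    "load_order_durations",
    "load_study_periods",
]

_DATA = resources.files("windcurtail") / "data"


def load_identification_counts() -> dict[str, ConfusionCounts]:
    """Per-period confusion counts (records) from the reference deployment."""
    with resources.as_file(_DATA / "identification_counts.csv") as path:
        return read_counts_csv(path)


def load_order_counts() -> pd.DataFrame:
    """Curtailment-order counts per (period, target class, distance class)."""
    with resources.as_file(_DATA / "order_counts.csv") as path:
        return pd.read_csv(path)


def load_order_durations() -> pd.DataFrame:
    """Total virtual-curtailment hours per target class."""
    with resources.as_file(_DATA / "order_durations.csv") as path:
        return pd.read_csv(path)


def load_study_periods() -> list[TimePeriod]:
    """The five system-configuration periods of the reference deployment."""
    with resources.as_file(_DATA / "periods.yaml") as path:
        return load_periods(path)
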