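"""Summaries of curtailment orders: pairing with determinations, per-week
standardization, distance-class tables and effectiveness proportions.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .engine import (
    DISTANCE_FAR,
    DISTANCE_NEAR,
    DISTANCE_WITHIN,
    CurtailmentOrder,
)
from .geometry import CoverageClass
from .identification import TimePeriod
from .records import EAGLE, NO_IMAGE, NON_EAGLE

logger = logging.getLogger(__name__)

__all__ = [
    "DISTANCE_CLASSES",
    "pair_orders_with_determinations",
    "period_weeks",
    "summarize",
    "effectiveness_metrics",
]

DISTANCE_CLASSES = (DISTANCE_FAR, DISTANCE_NEAR, DISTANCE_WITHIN)
TARGET_CLASSES = (EAGLE, NON_EAGLE)


def pair_orders_with_determinations(
    orders: Sequence[CurtailmentOrder],
    determinations: Mapping[str, str],
) -> tuple[list[tuple[CurtailmentOrder, str]], int]:
    """Label each order with its track's determination.

    Orders on image-less tracks cannot be labelled; they are excluded and
    counted.  An order whose track has no determination at all is an error.
    Returns ``(paired, n_excluded)`` with ``len(paired) + n_excluded`` equal
    to the input count.
    """
    paired: list[tuple[CurtailmentOrder, str]] = []
    n_excluded = 0
    for order in orders:
        if order.track_id not in determinations:
            raise KeyError(f"order {order.order_id}: unknown track {order.track_id}")
        det = determinations[order.track_id]
        if det == NO_IMAGE:
            n_excluded += 1
        else:
            paired.append((order, det))
    if n_excluded:
        logger.info("excluded %d orders on image-less tracks", n_excluded)
    return paired, n_excluded


def period_weeks(period: TimePeriod, effective_days: int | None = None) -> float:
    """Length of a period in weeks: (inclusive days - excluded days) / 7.

    ``effective_days`` overrides the calendar count, for replicating reports
    whose implied period lengths differ slightly from calendar arithmetic.
    """
    days = period.n_days if effective_days is None else effective_days
    if days <= 0:
        raise ValueError(f"period {period.name} has non-positive length")
    return days / 7.0


def summarize(
    paired: Sequence[tuple[CurtailmentOrder, str]],
    periods: Sequence[TimePeriod],
    coverage: Mapping[str, CoverageClass | str] | None = None,
    effective_days: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Stratified order summary, zero-filled over all strata.

    One row per (period, target class[, coverage], distance class) with the
    order count, total duration in hours, and the per-week order rate.
    Orders are assigned to the period containing their start time; orders
    outside every period are dropped and logged.
    """
    cov_levels = None
    if coverage is not None:
        cov_levels = sorted({str(CoverageClass(c).value) for c in coverage.values()})

    index_cols = ["period", "target_class"] + (["coverage"] if coverage is not None else []) + [
        "distance_class"
    ]
    rows: dict[tuple, dict] = {}
    for p in periods:
        for tc in TARGET_CLASSES:
            for cov in cov_levels or (None,):
                for dc in DISTANCE_CLASSES:
                    key = (p.name, tc) + ((cov,) if cov is not None else ()) + (dc,)
                    rows[key] = {"n_orders": 0, "total_duration_h": 0.0}

    n_dropped = 0
    for order, target_class in paired:
        period = next((p for p in periods if p.contains(order.start.date())), None)
        if period is None:
            n_dropped += 1
            continue
        key = (period.name, target_class)
        if coverage is not None:
            key += (str(CoverageClass(coverage[order.turbine_id]).value),)
        key += (order.distance_class,)
        rows[key]["n_orders"] += 1
        rows[key]["total_duration_h"] += order.duration_h
    if n_dropped:
        logger.info("summarize dropped %d orders outside all periods", n_dropped)

    weeks = {
        p.name: period_weeks(p, None if effective_days is None else effective_days.get(p.name))
        for p in periods
    }
    out = []
    for key, agg in rows.items():
        rec = dict(zip(index_cols, key))
        rec.update(agg)
        rec["rate_per_week"] = agg["n_orders"] / weeks[rec["period"]]
        out.append(rec)
    return pd.DataFrame(out, columns=index_cols + ["n_orders", "total_duration_h", "rate_per_week"])


def effectiveness_metrics(summary: pd.DataFrame) -> dict[str, float]:
    """Effectiveness proportions from a stratified order summary.

    Works on any table with ``target_class``, ``distance_class`` and
    ``n_orders`` columns (a :func:`summarize` output or a pre-counted
    table).  ``eagle_at_risk_share`` uses eagle orders as its denominator:
    the share of eagle orders whose target came within 100 m of, or entered,
    the rotor-swept zone.
    """
    n_by = summary.groupby("target_class")["n_orders"].sum()
    n_eagle = int(n_by.get(EAGLE, 0))
    n_noneagle = int(n_by.get(NON_EAGLE, 0))
    n_total = n_eagle + n_noneagle
    if n_total == 0:
        raise ValueError("empty summary: effectiveness undefined")

    def n(target_class: str, distance_classes: tuple[str, ...]) -> int:
        mask = (summary["target_class"] == target_class) & summary["distance_class"].isin(
            distance_classes
        )
        return int(summary.loc[mask, "n_orders"].sum())

    eagle_within = n(EAGLE, (DISTANCE_WITHIN,))
    eagle_at_risk = n(EAGLE, (DISTANCE_NEAR, DISTANCE_WITHIN))
    metrics = {
        "n_orders": float(n_total),
        "n_eagle_orders": float(n_eagle),
        "n_noneagle_orders": float(n_noneagle),
        "eagle_within_share": eagle_within / n_total,
        "eagle_at_risk_share": eagle_at_risk / n_eagle if n_eagle else float("nan"),
        "noneagle_to_eagle_ratio": n_noneagle / n_eagle if n_eagle else float("inf"),
        "noneagle_far_share": (
            n(NON_EAGLE, (DISTANCE_FAR,)) / n_noneagle if n_noneagle else float("nan")
        ),
        "eagle_far_share": n(EAGLE, (DISTANCE_FAR,)) / n_eagle if n_eagle else float("nan"),
    }
    return metrics
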