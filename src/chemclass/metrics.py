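"""Contingency-table metrics, macro/micro aggregation and method comparison.

Conventions: a metric with an empty denominator (e.g. precision when the
program predicts nothing positive) is reported as 0.0 and flagged as
undefined — a classifier that never fires should not score precision 1.
Macro aggregation averages per-class metrics (undefined entering as 0);
micro aggregation pools the raw counts first and derives metrics once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ContingencyTable",
    "MetricSet",
    "derive_metrics",
    "macro_metrics",
    "micro_metrics",
    "compare_methods",
    "MethodComparison",
    "performance_groups",
]

METRIC_NAMES = ("precision", "recall", "f1", "accuracy", "npv")


@dataclass(frozen=True)
class ContingencyTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    accuracy: float
    npv: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def derive_metrics(table: ContingencyTable) -> MetricSet:
    """Precision, recall, F1, accuracy and NPV from raw counts.

    F1 is the harmonic mean 2PR/(P+R); any 0/0 is reported as 0 with the
    metric name recorded in ``undefined``.
    """
    undefined: set[str] = set()
    p = _ratio(table.tp, table.tp + table.fp, "precision", undefined)
    r = _ratio(table.tp, table.tp + table.fn, "recall", undefined)
    if p + r == 0:
        f1 = 0.0
        undefined.add("f1")
    else:
        f1 = 2 * p * r / (p + r)
    acc = _ratio(table.tp + table.tn, table.total, "accuracy", undefined)
    npv = _ratio(table.tn, table.tn + table.fn, "npv", undefined)
    return MetricSet(p, r, f1, acc, npv, frozenset(undefined))


def macro_metrics(tables: Mapping[str, ContingencyTable]) -> MetricSet:
    """Unweighted mean of each per-class metric over all evaluated classes."""
    if not tables:
        raise ValueError("macro_metrics needs at least one class")
    per_class = [derive_metrics(t) for t in tables.values()]
    n = len(per_class)
    means = {name: sum(getattr(m, name) for m in per_class) / n for name in METRIC_NAMES}
    return MetricSet(**means)


def micro_metrics(tables: Mapping[str, ContingencyTable]) -> MetricSet:
    """Pool all counts into one table, then derive metrics from the pool."""
    if not tables:
        raise ValueError("micro_metrics needs at least one class")
    pooled = ContingencyTable()
    for t in tables.values():
        pooled = pooled + t
    return derive_metrics(pooled)


@dataclass
class MethodComparison:
    """Per-class F1 comparison between two methods with a practical margin."""

    per_class: dict[str, tuple[float, float, float, str]]  # id -> (fa, fb, delta, favored)
    margin: float

    @property
    def favored_counts(self) -> dict[str, int]:
        counts = {"A": 0, "B": 0, "neither": 0}
        for _, _, _, favored in self.per_class.values():
            counts[favored] += 1
        return counts

    def favored_ids(self, side: str) -> list[str]:
        return sorted(cid for cid, rec in self.per_class.items() if rec[3] == side)


def compare_methods(
    f1_a: Mapping[str, float], f1_b: Mapping[str, float], margin: float = 0.05
) -> MethodComparison:
    """Label each shared class A-favored (delta > margin), B-favored
    (delta < -margin) or neither."""
    shared = sorted(set(f1_a) & set(f1_b))
    if not shared:
        raise ValueError("compare_methods: methods share no classes")
    per_class = {}
    for cid in shared:
        fa, fb = f1_a[cid], f1_b[cid]
        delta = fa - fb
        if delta > margin:
            favored = "A"
        elif delta < -margin:
            favored = "B"
        else:
            favored = "neither"
        per_class[cid] = (fa, fb, delta, favored)
    return MethodComparison(per_class=per_class, margin=margin)


def performance_groups(f1: Mapping[str, float]) -> dict[str, set[str]]:
    """Partition classes by F1: poor (< 0.5), moderate (0.5–0.7, boundaries
    inclusive), good (> 0.7)."""
    groups: dict[str, set[str]] = {"poor": set(), "moderate": set(), "good": set()}
    for cid, value in f1.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{cid}: F1 {value} outside [0, 1]")
        if value < 0.5:
            groups["poor"].add(cid)
        elif value > 0.7:
            groups["good"].add(cid)
        else:
            groups["moderate"].add(cid)
    return groups
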