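"""Nonparametric enrichment of descriptors against method performance.

Classes are summarised by the median of each descriptor over their member
structures; two groups of classes (e.g. those where the learned programs
beat a comparator by more than 0.05 F1, versus those where the comparator
wins) are then compared descriptor-by-descriptor with two-sided
Mann-Whitney U tests, Benjamini-Hochberg FDR correction across the panel,
and Cliff's delta effect sizes.  The sign convention: positive delta means
higher descriptor values in group A (the first group, conventionally the
program-favored classes); negative delta means higher values in group B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "cliffs_delta",
    "delta_magnitude",
    "bh_fdr",
    "mann_whitney",
    "class_profiles",
    "enrichment_analysis",
]

# |delta| cut points for the conventional magnitude labels
_MAGNITUDE_CUTS = ((0.147, "negligible"), (0.33, "small"), (0.474, "medium"))


@dataclass(frozen=True)
class EnrichmentResult:
    descriptor: str
    u_statistic: float
    p_value: float
    q_value: float
    cliffs_delta: float
    magnitude: str
    significant: bool

    @property
    def direction(self) -> str:
        if self.cliffs_delta > 0:
            return "higher in group A"
        if self.cliffs_delta < 0:
            return "higher in group B"
        return "no direction"


def delta_magnitude(delta: float) -> str:
    """Magnitude label from |delta|: negligible < 0.147 <= small < 0.33 <=
    medium < 0.474 <= large."""
    a = abs(delta)
    for cut, label in _MAGNITUDE_CUTS:
        if a < cut:
            return label
    return "large"


def cliffs_delta(a: Sequence[float], b: Sequence[float]) -> tuple[float, str]:
    """Cliff's delta: (#{x>y} - #{x<y}) / (|a|·|b|) over all pairs (x in a,
    y in b), with its magnitude label.  Positive values mean the first
    sample tends to be larger."""
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("cliffs_delta requires two nonempty samples")
    diff = xa[:, None] - xb[None, :]
    delta = float((np.sign(diff)).sum() / (xa.size * xb.size))
    return delta, delta_magnitude(delta)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q_values, significant_flags) aligned with the input order;
    significant iff q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first sample, p value).

    Exact null distribution for small untied samples (both n <= 8);
    otherwise the normal approximation with tie correction.  Two constant,
    identical samples are reported as U = nm/2, p = 1.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("mann_whitney requires two nonempty samples")
    pooled = np.concatenate([xa, xb])
    if np.all(pooled == pooled[0]):
        return xa.size * xb.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(xa.size, xb.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def class_profiles(
    descriptor_matrix: pd.DataFrame, members: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-class median descriptor profiles.

    ``descriptor_matrix`` is structures x descriptors (index: structure id);
    ``members`` maps class id -> member structure ids.  Structures missing
    from the matrix (e.g. unparseable SMILES) are skipped; a class with no
    usable members is dropped.
    """
    rows = {}
    for class_id, ids in members.items():
        idx = [i for i in ids if i in descriptor_matrix.index]
        if not idx:
            continue
        rows[class_id] = descriptor_matrix.loc[idx].median(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")[descriptor_matrix.columns]


def enrichment_analysis(
    profiles: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-descriptor Mann-Whitney U of group A vs group B class profiles,
    BH-corrected across the descriptor panel, with Cliff's delta.

    Results are sorted by q value, then by decreasing |delta| (ready for a
    volcano-style ranking).  Groups must be disjoint with >= 2 classes each.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("groups must be disjoint")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each group needs at least two classes")
    missing = (set_a | set_b) - set(profiles.index)
    if missing:
        raise KeyError(f"classes missing from profiles: {sorted(missing)[:5]}")
    a_frame = profiles.loc[sorted(set_a)]
    b_frame = profiles.loc[sorted(set_b)]

    names, u_stats, p_values, deltas, magnitudes = [], [], [], [], []
    for descriptor in profiles.columns:
        va = a_frame[descriptor].to_numpy()
        vb = b_frame[descriptor].to_numpy()
        u, p = mann_whitney(va, vb)
        delta, magnitude = cliffs_delta(va, vb)
        names.append(descriptor)
        u_stats.append(u)
        p_values.append(p)
        deltas.append(delta)
        magnitudes.append(magnitude)
    q_values, significant = bh_fdr(p_values, alpha=alpha)
    results = [
        EnrichmentResult(
            descriptor=n, u_statistic=u, p_value=p, q_value=float(q),
            cliffs_delta=d, magnitude=m, significant=bool(s),
        )
        for n, u, p, q, d, m, s in zip(
            names, u_stats, p_values, q_values, deltas, magnitudes, significant
        )
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.cliffs_delta), r.descriptor))
    return results
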