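"""plDDT-based confidence categories, reranking and tabulation.

Predictions are rescored by the percentage of confident residues
(per-residue plDDT >= 70).  Category thresholds on that percentage:
Medium >= 70%, Good >= 80%, High >= 90%.  Rank pools Top1 / Top10 / All
are prefixes of the deterministic reranked order.  An exact one-sided
binomial test supports enrichment comparisons between pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assessment import ModelAssessment

MEDIUM, GOOD, HIGH, UNCLASSIFIED = "MEDIUM", "GOOD", "HIGH", "UNCLASSIFIED"
RANK_POOLS = ("Top1", "Top10", "All")
CATEGORY_POOLS = ("All", "Medium", "Good", "High")

_CATEGORY_MIN_FRACTION = {"Medium": 70.0, "Good": 80.0, "High": 90.0}


@dataclass
class ConfidenceRecord:
    model_id: str
    confidence_fraction: float  # percent of residues with plDDT >= 70
    mean_plddt: float
    category: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        self.category = categorize(self.confidence_fraction)


def confidence_fraction(plddts: Sequence[float]) -> float:
    """Percent of residues with plDDT >= 70 (the boundary is confident)."""
    arr = np.asarray(plddts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty plDDT sequence")
    return 100.0 * float((arr >= 70.0).mean())


def categorize(fraction: float) -> str:
    """Highest threshold met: >=90 HIGH, >=80 GOOD, >=70 MEDIUM."""
    if not (0.0 <= fraction <= 100.0):
        raise ValueError(f"fraction {fraction} outside [0, 100]")
    if fraction >= 90.0:
        return HIGH
    if fraction >= 80.0:
        return GOOD
    if fraction >= 70.0:
        return MEDIUM
    return UNCLASSIFIED


def rerank(records: Sequence[ConfidenceRecord]) -> list[ConfidenceRecord]:
    """Deterministic confidence order: descending confidence fraction,
    ties by descending mean plDDT, then lexicographic model id."""
    if not records:
        raise ValueError("no records to rank")
    return sorted(
        records,
        key=lambda r: (-r.confidence_fraction, -r.mean_plddt, r.model_id),
    )


@dataclass
class CategoryTabulation:
    """N_ij counts per rank pool x confidence pool x label.

    Confidence pools are cumulative (Medium contains Good contains High);
    'predicted' flags follow the N_ij >= 1 rule.
    """

    counts: dict[tuple[str, str, str], int]
    n_models: int

    def predicted(self, rank_pool: str, category_pool: str, label: str) -> bool:
        return self.counts.get((rank_pool, category_pool, label), 0) >= 1

    def pool_fraction(self, rank_pool: str, label: str,
                      category_pool: str = "All") -> float | None:
        total = sum(
            v for (rp, cp, _lab), v in self.counts.items()
            if rp == rank_pool and cp == category_pool
        )
        if total == 0:
            return None
        return self.counts.get((rank_pool, category_pool, label), 0) / total


def tabulate(
    ranked: Sequence[ConfidenceRecord],
    assessments: Mapping[str, ModelAssessment] | Sequence[ModelAssessment],
) -> CategoryTabulation:
    """Count models per (Top1/Top10/All) x (All/Medium/Good/High) x label."""
    if not isinstance(assessments, Mapping):
        assessments = {a.model_id: a for a in assessments}
    missing = [r.model_id for r in ranked if r.model_id not in assessments]
    if missing:
        raise KeyError(f"assessments missing for model ids: {', '.join(missing)}")
    counts: dict[tuple[str, str, str], int] = {}
    pools = {
        "Top1": list(ranked[:1]),
        "Top10": list(ranked[:10]),
        "All": list(ranked),
    }
    for rank_pool, members in pools.items():
        for rec in members:
            label = assessments[rec.model_id].label
            for cat_pool in CATEGORY_POOLS:
                if cat_pool != "All" and rec.confidence_fraction < _CATEGORY_MIN_FRACTION[cat_pool]:
                    continue
                key = (rank_pool, cat_pool, label)
                counts[key] = counts.get(key, 0) + 1
    return CategoryTabulation(counts=counts, n_models=len(ranked))


def binomial_onesided(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """Exact one-sided binomial tail probability.

    lower: P(X <= k); upper: P(X >= k) for X ~ Binomial(n, p0).
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if tail == "lower":
        return float(stats.binom.cdf(k, n, p0))
    if tail == "upper":
        return float(stats.binom.sf(k - 1, n, p0))
    raise ValueError("tail must be 'lower' or 'upper'")


def records_from_assessments(
    assessments: Sequence[ModelAssessment],
) -> list[ConfidenceRecord]:
    """Build confidence records from assessments carrying plDDT statistics."""
    out = []
    for a in assessments:
        if a.confidence_fraction is None or a.mean_plddt is None:
            raise ValueError(f"model {a.model_id} lacks plDDT statistics")
        out.append(ConfidenceRecord(a.model_id, a.confidence_fraction, a.mean_plddt))
    return out
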