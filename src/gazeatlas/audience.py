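"""Audience-level diagnostics: stratified first-hit tables, subgroup-minus-
overall delta matrices, and the early-vs-sticky quadrant classification.

Subgroup deltas are reported as subgroup minus overall, in percentage
points, so a positive value means the subgroup's first fixations land on
that category more often than the audience as a whole.

The early-vs-sticky view crosses each AOI's first-hit share (early capture)
with its dwell-dominance score S (stickiness). "Early" means at or above
the within-ad median first-hit share; "sticky" means S strictly above 0.
The four quadrants map to design actions: protect (early + sticky),
promote (late + sticky: move it earlier), unclutter (early + not sticky),
reconsider (neither).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from gazeatlas.core import ValidationError
from gazeatlas.dominance import DominanceRanking
from gazeatlas.metrics import FirstHitResult, first_hit_distribution

__all__ = [
    "DeltaMatrix",
    "QuadrantAssignment",
    "QUADRANT_ACTIONS",
    "stratified_first_hit",
    "delta_matrix",
    "classify_quadrants",
]

#: Quadrant -> recommended design action.
QUADRANT_ACTIONS: Mapping[str, str] = {
    "early_sticky": "protect",
    "late_sticky": "promote",
    "early_not_sticky": "unclutter",
    "neither": "reconsider",
}


@dataclass
class DeltaMatrix:
    """Subgroup-minus-overall first-hit differences (percentage points).

    Rows are categories, columns are stratum levels; each column sums to
    ~0 because both distributions sum to 100%.
    """

    ad_id: str
    dimension: str
    categories: list[str]
    levels: list[str]
    values: np.ndarray  # categories x levels, percentage points
    sign_convention: str = "subgroup - overall"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.categories, columns=self.levels)


@dataclass(frozen=True)
class QuadrantAssignment:
    """One AOI's position in the early-vs-sticky plane and its action."""

    ad_id: str
    aoi_id: str
    first_hit_pct: float
    S: float
    quadrant: str
    action: str


def stratified_first_hit(
    results: Sequence[FirstHitResult],
    strata: Mapping[str, str],
    level: Literal["aoi", "category"] = "category",
) -> dict[str, dict[str, float]]:
    """First-hit distributions within each stratum level.

    ``strata`` maps participant_id -> level. Every participant appearing in
    the results must be mapped; levels whose trials are all censored are
    omitted (they support no distribution).
    """
    unknown = sorted({r.participant_id for r in results} - set(strata))
    if unknown:
        raise ValidationError(f"participants missing from strata map: {unknown}")
    by_level: dict[str, list[FirstHitResult]] = defaultdict(list)
    for r in results:
        by_level[strata[r.participant_id]].append(r)
    out: dict[str, dict[str, float]] = {}
    for lvl in sorted(by_level):
        rs = by_level[lvl]
        if all(r.aoi_id is None for r in rs):
            continue  # no first hit in this level: nothing to distribute
        out[lvl] = first_hit_distribution(rs, level=level)
    return out


def delta_matrix(
    subgroup_dists: Mapping[str, Mapping[str, float]],
    overall_dist: Mapping[str, float],
    ad_id: str = "",
    dimension: str = "",
) -> DeltaMatrix:
    """Delta = subgroup - overall first-hit percentage, per category x level.

    Categories missing from either distribution are treated as 0%.
    """
    categories = sorted(set(overall_dist) | {c for d in subgroup_dists.values() for c in d})
    levels = sorted(subgroup_dists)
    values = np.zeros((len(categories), len(levels)))
    for j, lvl in enumerate(levels):
        sub = subgroup_dists[lvl]
        for i, cat in enumerate(categories):
            values[i, j] = sub.get(cat, 0.0) - overall_dist.get(cat, 0.0)
    return DeltaMatrix(
        ad_id=ad_id, dimension=dimension, categories=categories, levels=levels, values=values
    )


def classify_quadrants(
    first_hit_pct: Mapping[str, float],
    ranking: DominanceRanking,
) -> list[QuadrantAssignment]:
    """Cross first-hit share with dominance score into design quadrants.

    ``first_hit_pct`` should cover every ranked AOI (AOIs never hit first
    carry 0%). The vertical reference is the within-ad median of the
    supplied first-hit shares; the horizontal reference is S = 0. The
    boundary rule is deterministic: at the median counts as early, S = 0
    counts as not sticky.
    """
    keys = [k for k in ranking.keys if not math.isnan(ranking.scores[k])]
    missing = sorted(set(keys) - set(first_hit_pct))
    if missing:
        raise ValidationError(f"first-hit percentages missing for AOIs: {missing}")
    median_pct = float(np.median([first_hit_pct[k] for k in keys]))
    out = []
    for k in sorted(keys):
        pct = first_hit_pct[k]
        s = ranking.scores[k]
        early = pct >= median_pct
        sticky = s > 0
        quadrant = (
            "early_sticky"
            if early and sticky
            else "late_sticky"
            if sticky
            else "early_not_sticky"
            if early
            else "neither"
        )
        out.append(
            QuadrantAssignment(
                ad_id=ranking.ad_id,
                aoi_id=k,
                first_hit_pct=pct,
                S=s,
                quadrant=quadrant,
                action=QUADRANT_ACTIONS[quadrant],
            )
        )
    return out
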