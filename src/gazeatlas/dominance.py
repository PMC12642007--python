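"""Tie-aware pairwise dwell-dominance matrices, dominance scores, category
dominance, TTFF precedence, support masking, axiom checks, and concordance.

For each AOI pair (i, j) within an ad, restricted to participants who
fixated BOTH AOIs, the win probability is

    P_ij = (#{fd_i > fd_j} + 0.5 * #{fd_i = fd_j}) / N_ij,

where N_ij is the number of such joint observers. By construction the
matrix has P_ii = 0.5 and P_ij + P_ji = 1 wherever defined. Each key's
dominance score is S_i = 2 * (mean_j P_ij - 0.5), the mean taken over
defined off-diagonal pairs only, giving S in [-1, 1]: +1 wins every
contest, -1 loses every contest, 0 is a coin flip on average. Low-support
cells (N < 5 by default) are masked in figures only; they stay in every
algebraic computation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gazeatlas.core import AttentionRecord, Category, ValidationError
from gazeatlas.metrics import BenchmarkRow

__all__ = [
    "PairwiseMatrix",
    "DominanceRanking",
    "ConcordanceReport",
    "AxiomReport",
    "pairwise_dwell_matrix",
    "dominance_scores",
    "category_dominance",
    "ttff_precedence_matrix",
    "apply_support_mask",
    "verify_axioms",
    "concordance",
]


@dataclass
class PairwiseMatrix:
    """A square tie-aware win-probability matrix with its support counts.

    ``P[i, j]`` is the probability that key i beats key j; undefined pairs
    (no joint observers) are NaN. ``N[i, j]`` counts the participants
    contributing to the pair; ``N[i, i]`` counts the observers of key i.
    ``mask`` flags low-support cells for display only.
    """

    ad_id: str
    keys: list[str]
    P: np.ndarray
    N: np.ndarray
    kind: Literal["dwell", "precedence"] = "dwell"
    mask_threshold: int = 5
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        k = len(self.keys)
        if self.P.shape != (k, k) or self.N.shape != (k, k):
            raise ValidationError("P and N must be K x K for K keys")

    @property
    def size(self) -> int:
        return len(self.keys)

    def defined(self) -> np.ndarray:
        """Boolean matrix of defined (non-NaN) entries."""
        return ~np.isnan(self.P)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form export: one row per (key_i, key_j) cell."""
        mask = self.mask if self.mask is not None else np.zeros_like(self.N, dtype=bool)
        rows = []
        for i, ki in enumerate(self.keys):
            for j, kj in enumerate(self.keys):
                rows.append(
                    {
                        "ad_id": self.ad_id,
                        "key_i": ki,
                        "key_j": kj,
                        "P": self.P[i, j],
                        "N": int(self.N[i, j]),
                        "masked": bool(mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_grid_text(self, decimals: int = 3) -> str:
        """Square-grid text rendering for quick inspection."""
        width = max(8, max(len(k) for k in self.keys) + 1)
        header = " " * width + "".join(f"{k:>{width}}" for k in self.keys)
        lines = [header]
        for i, ki in enumerate(self.keys):
            cells = []
            for j in range(self.size):
                v = self.P[i, j]
                cells.append(f"{'--':>{width}}" if np.isnan(v) else f"{v:>{width}.{decimals}f}")
            lines.append(f"{ki:>{width}}" + "".join(cells))
        return "\n".join(lines)


@dataclass
class DominanceRanking:
    """Per-key dominance score S in [-1, 1] and rank (1 = highest S)."""

    ad_id: str
    keys: list[str]
    scores: dict[str, float]  # NaN for isolated keys (no defined pairs)
    ranks: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def ordered_keys(self) -> list[str]:
        return sorted(
            [k for k in self.keys if not math.isnan(self.scores[k])],
            key=lambda k: self.ranks[k],
        )


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between dominance scores and median dwell per key."""

    ad_id: str
    pearson_r: float
    spearman_rho: float
    n_keys: int


@dataclass(frozen=True)
class AxiomReport:
    """Result of the construction-axiom check on a pairwise matrix."""

    ad_id: str
    passed: bool
    max_offdiag_deviation: float
    max_diag_deviation: float
    tol: float


def _single_ad(records: Sequence[AttentionRecord]) -> str:
    ads = {r.ad_id for r in records}
    if len(ads) != 1:
        raise ValidationError(f"records span multiple ads: {sorted(ads)}")
    return next(iter(ads))


def _pairwise_from_values(
    ad_id: str,
    values: dict[str, dict[str, float]],
    kind: Literal["dwell", "precedence"],
    mask_threshold: int,
) -> PairwiseMatrix:
    """Build the matrix from participant -> {key: value} with higher = win."""
    keys = sorted({k for per in values.values() for k in per})
    if len(keys) < 2:
        raise ValidationError(f"need >= 2 keys to compare, got {keys}")
    k = len(keys)
    idx = {key: i for i, key in enumerate(keys)}
    P = np.full((k, k), np.nan)
    N = np.zeros((k, k), dtype=int)
    np.fill_diagonal(P, 0.5)
    for key, i in idx.items():
        N[i, i] = sum(1 for per in values.values() if key in per)
    for a in range(k):
        for b in range(a + 1, k):
            ka, kb = keys[a], keys[b]
            wins = ties = n = 0
            for per in values.values():
                if ka in per and kb in per:
                    n += 1
                    if per[ka] > per[kb]:
                        wins += 1
                    elif per[ka] == per[kb]:
                        ties += 1
            if n > 0:
                p = (wins + 0.5 * ties) / n
                P[a, b] = p
                P[b, a] = 1.0 - p
                N[a, b] = N[b, a] = n
    return PairwiseMatrix(ad_id=ad_id, keys=keys, P=P, N=N, kind=kind, mask_threshold=mask_threshold)


def pairwise_dwell_matrix(
    records: Sequence[AttentionRecord],
    level: Literal["aoi", "category"] = "aoi",
    mask_threshold: int = 5,
) -> PairwiseMatrix:
    """Tie-aware pairwise dwell-dominance matrix for one ad.

    Only participants with uncensored dwell on BOTH members of a pair
    contribute to it; ties count one half. Pairs with no joint observer are
    undefined (NaN), which is distinct from display masking.

    At ``level="category"`` dwell is first summed within category per
    participant (a participant observes a category iff it has at least one
    uncensored AOI there).
    """
    ad_id = _single_ad(records)
    values: dict[str, dict[str, float]] = defaultdict(dict)
    if level == "aoi":
        for r in records:
            if not r.censored:
                values[r.participant_id][r.aoi_id] = r.fd_ms
    elif level == "category":
        for r in records:
            if not r.censored:
                cat = r.category.value
                values[r.participant_id][cat] = values[r.participant_id].get(cat, 0.0) + r.fd_ms
    else:
        raise ValidationError(f"unknown level {level!r}")
    return _pairwise_from_values(ad_id, values, "dwell", mask_threshold)


def category_dominance(
    records: Sequence[AttentionRecord], mask_threshold: int = 5
) -> PairwiseMatrix:
    """Category-level dwell dominance (dwell aggregated within category).

    Categories absent from the ad are simply absent from the matrix.
    """
    matrix = pairwise_dwell_matrix(records, level="category", mask_threshold=mask_threshold)
    return matrix


def ttff_precedence_matrix(
    records: Sequence[AttentionRecord],
    level: Literal["aoi", "category"] = "category",
    mask_threshold: int = 5,
) -> PairwiseMatrix:
    """Pairwise TTFF precedence matrix: an earlier first fixation is a win.

    A participant contributes to pair (i, j) when at least one of the two is
    uncensored; an uncensored key beats a censored one, equal latencies tie
    at 0.5, and participants censored on both are excluded. At the category
    level a participant's TTFF for a category is the minimum uncensored TTFF
    over its AOIs.
    """
    ad_id = _single_ad(records)
    # latency per participant per key; censored keys omitted
    latency: dict[str, dict[str, float]] = defaultdict(dict)
    keys_all: set[str] = set()
    for r in records:
        key = r.aoi_id if level == "aoi" else r.category.value
        keys_all.add(key)
        if not r.censored:
            cur = latency[r.participant_id].get(key)
            if cur is None or r.ttff_ms < cur:
                latency[r.participant_id][key] = r.ttff_ms
    keys = sorted(keys_all)
    if len(keys) < 2:
        raise ValidationError(f"need >= 2 keys to compare, got {keys}")
    k = len(keys)
    P = np.full((k, k), np.nan)
    N = np.zeros((k, k), dtype=int)
    np.fill_diagonal(P, 0.5)
    all_participants = sorted({r.participant_id for r in records})
    for key, i in ((key, keys.index(key)) for key in keys):
        N[i, i] = sum(1 for p in all_participants if key in latency.get(p, {}))
    for a in range(k):
        for b in range(a + 1, k):
            ka, kb = keys[a], keys[b]
            wins = ties = n = 0
            for p in all_participants:
                ta = latency.get(p, {}).get(ka)
                tb = latency.get(p, {}).get(kb)
                if ta is None and tb is None:
                    continue  # both censored: no information
                n += 1
                if tb is None:
                    wins += 1  # uncensored beats censored
                elif ta is None:
                    pass  # loss for ka
                elif ta < tb:
                    wins += 1
                elif ta == tb:
                    ties += 1
            if n > 0:
                p_ab = (wins + 0.5 * ties) / n
                P[a, b] = p_ab
                P[b, a] = 1.0 - p_ab
                N[a, b] = N[b, a] = n
    return PairwiseMatrix(
        ad_id=ad_id, keys=keys, P=P, N=N, kind="precedence", mask_threshold=mask_threshold
    )


def dominance_scores(matrix: PairwiseMatrix) -> DominanceRanking:
    """Dominance score S_i = 2 * (mean defined off-diagonal P_ij - 0.5).

    The mean excludes the diagonal (its fixed 0.5 would shrink every score
    toward zero) and undefined pairs. A key with no defined pair gets a NaN
    score, reported via ``warnings``. Ranks order by descending S with
    lexicographic tie-break; when every pair is defined the scores sum to 0.
    """
    k = matrix.size
    scores: dict[str, float] = {}
    warnings: list[str] = []
    for i, key in enumerate(matrix.keys):
        off = np.concatenate([matrix.P[i, :i], matrix.P[i, i + 1 :]])
        defined = off[~np.isnan(off)]
        if defined.size == 0:
            scores[key] = math.nan
            warnings.append(f"key {key!r} has no defined pairwise comparison; score undefined")
        else:
            scores[key] = float(2.0 * (defined.mean() - 0.5))
    ranked = sorted(
        (key for key in matrix.keys if not math.isnan(scores[key])),
        key=lambda key: (-scores[key], key),
    )
    ranks = {key: r + 1 for r, key in enumerate(ranked)}
    return DominanceRanking(
        ad_id=matrix.ad_id, keys=list(matrix.keys), scores=scores, ranks=ranks, warnings=warnings
    )


def apply_support_mask(matrix: PairwiseMatrix, threshold: int = 5) -> PairwiseMatrix:
    """Flag low-support cells (N < threshold) for display.

    P, N, and every downstream score are unchanged: masking is a figure
    convention, not an algebraic one. The diagonal is never masked.
    """
    mask = matrix.N < threshold
    np.fill_diagonal(mask, False)
    return replace(matrix, mask=mask, mask_threshold=threshold)


def verify_axioms(matrix: PairwiseMatrix, tol: float = 1e-12) -> AxiomReport:
    """Check the construction axioms P_ij + P_ji = 1 (defined off-diagonal
    pairs) and P_ii = 0.5, reporting maximum deviations."""
    P = matrix.P
    k = matrix.size
    off_dev = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if not (np.isnan(P[i, j]) or np.isnan(P[j, i])):
                off_dev = max(off_dev, abs(P[i, j] + P[j, i] - 1.0))
    diag_dev = float(np.max(np.abs(np.diag(P) - 0.5))) if k else 0.0
    return AxiomReport(
        ad_id=matrix.ad_id,
        passed=(off_dev <= tol and diag_dev <= tol),
        max_offdiag_deviation=off_dev,
        max_diag_deviation=diag_dev,
        tol=tol,
    )


def concordance(
    ranking: DominanceRanking, benchmark: Sequence[BenchmarkRow]
) -> ConcordanceReport:
    """Pearson/Spearman correlation of dominance scores against median dwell.

    Keys are matched between the ranking and the benchmark rows (same ad);
    fewer than 3 shared keys is an error, zero variance yields NaN
    coefficients.
    """
    med = {b.key: b.median_fd_ms for b in benchmark if b.ad_id == ranking.ad_id}
    shared = [
        k for k in ranking.keys if k in med and not math.isnan(ranking.scores[k])
    ]
    if len(shared) < 3:
        raise ValidationError(
            f"concordance needs >= 3 shared keys, got {len(shared)} for ad {ranking.ad_id!r}"
        )
    s = np.array([ranking.scores[k] for k in shared])
    d = np.array([med[k] for k in shared])
    if np.allclose(s, s[0]) or np.allclose(d, d[0]):
        return ConcordanceReport(ranking.ad_id, math.nan, math.nan, len(shared))
    pearson = float(stats.pearsonr(s, d).statistic)
    spearman = float(stats.spearmanr(s, d).statistic)
    return ConcordanceReport(ranking.ad_id, pearson, spearman, len(shared))
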