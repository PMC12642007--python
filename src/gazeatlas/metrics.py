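"""Core AOI attention metrics: TTFF with right-censoring, fixation count,
dwell, first-hit determination, and benchmark summary tables.

Metrics live at the participant x ad x AOI level. An AOI never fixated
within the exposure gets a right-censored TTFF equal to the censor value
(default 10,000 ms) and zeroed FC/FD. The first hit of a trial is the AOI
with the minimum uncensored TTFF; censored AOIs never determine the first
hit but their censor value is included in latency summaries.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gazeatlas.core import (
    CATEGORY_PRIORITY,
    AttentionRecord,
    Category,
    FixationRecord,
    StudyTable,
    ValidationError,
)
from gazeatlas.geometry import AOIDefinition

__all__ = [
    "FirstHitResult",
    "BenchmarkRow",
    "compute_aoi_metrics",
    "first_hit",
    "first_hit_distribution",
    "benchmark_table",
    "benchmark_frame",
    "group_summary",
]

Level = Literal["aoi", "category"]


@dataclass(frozen=True)
class FirstHitResult:
    """The first-fixated AOI of one trial (None when every AOI is censored)."""

    participant_id: str
    ad_id: str
    aoi_id: Optional[str]
    category: Optional[Category]
    ttff_ms: float


@dataclass(frozen=True)
class BenchmarkRow:
    """Median/IQR summary of the three metrics for one ad x AOI (or category)."""

    ad_id: str
    key: str
    median_ttff_ms: float
    iqr_ttff_ms: float
    median_fc: float
    iqr_fc: float
    median_fd_ms: float
    iqr_fd_ms: float
    n: int


def compute_aoi_metrics(
    fixations: Sequence[FixationRecord],
    aois: Sequence[AOIDefinition],
    exposure_ms: float = 10_000.0,
    censor_ms: float = 10_000.0,
    strata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[AttentionRecord]:
    """Aggregate one trial's assigned fixations into per-AOI attention records.

    One record is always emitted per AOI of the ad: TTFF is the onset of the
    earliest fixation inside the AOI, FC the count of fixations, FD their
    summed duration; AOIs with no fixation are right-censored. Fixations
    whose ``aoi_id`` is None (landed outside every AOI) contribute nothing.

    ``strata`` optionally maps participant_id -> {age_band, household,
    education} labels to carry onto the records.
    """
    if not aois:
        raise ValidationError("no AOIs supplied")
    ad_ids = {a.ad_id for a in aois}
    if len(ad_ids) != 1:
        raise ValidationError(f"AOIs span multiple ads: {sorted(ad_ids)}")
    (ad_id,) = ad_ids
    trial_keys = {(f.participant_id, f.ad_id) for f in fixations}
    if len(trial_keys) > 1:
        raise ValidationError(f"fixations span multiple trials: {sorted(trial_keys)}")
    if fixations:
        participant_id, fix_ad = next(iter(trial_keys))
        if fix_ad != ad_id:
            raise ValidationError(f"fixations are for ad {fix_ad!r}, AOIs for {ad_id!r}")
    else:
        raise ValidationError("cannot derive participant identity from an empty trial")

    known = {a.aoi_id for a in aois}
    per_aoi: dict[str, list[FixationRecord]] = defaultdict(list)
    for f in fixations:
        if f.aoi_id is None:
            continue
        if f.aoi_id not in known:
            raise ValidationError(f"fixation references unknown AOI {f.aoi_id!r}")
        per_aoi[f.aoi_id].append(f)

    labels = (strata or {}).get(participant_id, {})
    records: list[AttentionRecord] = []
    for aoi in aois:
        hits = per_aoi.get(aoi.aoi_id, [])
        if hits:
            ttff = min(h.onset_ms for h in hits)
            rec = AttentionRecord(
                participant_id=participant_id,
                ad_id=ad_id,
                aoi_id=aoi.aoi_id,
                category=aoi.category,
                ttff_ms=min(ttff, censor_ms),
                censored=False,
                fc=len(hits),
                fd_ms=sum(h.duration_ms for h in hits),
                age_band=labels.get("age_band", ""),
                household=labels.get("household", ""),
                education=labels.get("education", ""),
            )
        else:
            rec = AttentionRecord(
                participant_id=participant_id,
                ad_id=ad_id,
                aoi_id=aoi.aoi_id,
                category=aoi.category,
                ttff_ms=censor_ms,
                censored=True,
                fc=0,
                fd_ms=0.0,
                age_band=labels.get("age_band", ""),
                household=labels.get("household", ""),
                education=labels.get("education", ""),
            )
        records.append(rec)
    return records


def first_hit(records: Sequence[AttentionRecord]) -> FirstHitResult:
    """Return the first-hit AOI of one trial: the minimum uncensored TTFF.

    Exact TTFF ties (possible with discretized timestamps) are broken by the
    category overlap-priority order, then lexicographic AOI id. If every AOI
    is censored the result carries ``aoi_id=None`` and the trial drops out
    of first-hit denominators.
    """
    if not records:
        raise ValidationError("first_hit requires at least one record")
    keys = {(r.participant_id, r.ad_id) for r in records}
    if len(keys) != 1:
        raise ValidationError(f"records span multiple trials: {sorted(keys)}")
    participant_id, ad_id = next(iter(keys))
    live = [r for r in records if not r.censored]
    if not live:
        return FirstHitResult(participant_id, ad_id, None, None, records[0].ttff_ms)
    best = min(live, key=lambda r: (r.ttff_ms, CATEGORY_PRIORITY[r.category], r.aoi_id))
    return FirstHitResult(participant_id, ad_id, best.aoi_id, best.category, best.ttff_ms)


def first_hit_distribution(
    results: Sequence[FirstHitResult], level: Level = "category"
) -> dict[str, float]:
    """Share of trials whose first fixation landed on each AOI / category.

    Percentages are over trials with at least one uncensored AOI (no-hit
    trials are excluded from the denominator) and sum to exactly 100.
    Values are exact; round to one decimal at presentation time.
    """
    ads = {r.ad_id for r in results}
    if len(ads) > 1:
        raise ValidationError(f"results span multiple ads: {sorted(ads)}")
    hits = [r for r in results if r.aoi_id is not None]
    if not hits:
        raise ValidationError("no trial produced a first hit (all censored)")
    if level == "aoi":
        counts = Counter(r.aoi_id for r in hits)
    elif level == "category":
        counts = Counter(r.category.value for r in hits)
    else:
        raise ValidationError(f"unknown level {level!r}")
    n = len(hits)
    return {key: 100.0 * c / n for key, c in sorted(counts.items())}


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def benchmark_table(table: StudyTable, level: Level = "aoi") -> list[BenchmarkRow]:
    """Per ad x AOI (or category) medians and IQRs of TTFF, FC and FD.

    Censored TTFF values enter the latency summaries at the censor value;
    censored FC/FD enter as zeros. At the category level a participant's
    AOIs are first pooled (all records of the category contribute).
    """
    if not table.records:
        raise ValidationError("empty study table")
    df = pd.DataFrame(
        {
            "ad_id": [r.ad_id for r in table.records],
            "key": [
                r.aoi_id if level == "aoi" else r.category.value for r in table.records
            ],
            "participant_id": [r.participant_id for r in table.records],
            "ttff_ms": [r.ttff_ms for r in table.records],
            "fc": [r.fc for r in table.records],
            "fd_ms": [r.fd_ms for r in table.records],
        }
    )
    rows: list[BenchmarkRow] = []
    for (ad_id, key), g in df.groupby(["ad_id", "key"], sort=True):
        rows.append(
            BenchmarkRow(
                ad_id=ad_id,
                key=key,
                median_ttff_ms=float(g["ttff_ms"].median()),
                iqr_ttff_ms=_iqr(g["ttff_ms"].to_numpy()),
                median_fc=float(g["fc"].median()),
                iqr_fc=_iqr(g["fc"].to_numpy()),
                median_fd_ms=float(g["fd_ms"].median()),
                iqr_fd_ms=_iqr(g["fd_ms"].to_numpy()),
                n=int(g["participant_id"].nunique()),
            )
        )
    return rows


def benchmark_frame(rows: Sequence[BenchmarkRow]) -> pd.DataFrame:
    """Benchmark rows as a pandas frame ready for CSV export."""
    return pd.DataFrame([vars(r) for r in rows])


def group_summary(values: Sequence[float], confidence: float = 0.95) -> dict[str, float]:
    """Mean with a t-based confidence interval, for descriptive group plots."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("group_summary requires at least one value")
    mean = float(arr.mean())
    if arr.size == 1:
        return {"mean": mean, "ci_low": math.nan, "ci_high": math.nan, "n": 1}
    sem = stats.sem(arr)
    half = sem * stats.t.ppf(0.5 + confidence / 2.0, arr.size - 1)
    return {
        "mean": mean,
        "ci_low": mean - float(half),
        "ci_high": mean + float(half),
        "n": int(arr.size),
    }
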