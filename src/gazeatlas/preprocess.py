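"""Raw gaze preprocessing: I-VT fixation classification, fixation merging,
and trial-level quality control.

The velocity-threshold (I-VT) classifier labels a sample fixational when
its point-to-point angular velocity falls below a threshold (default
30 deg/s); maximal runs of fixational samples lasting at least the minimum
fixation duration become fixations. Adjacent fixations closer than 0.5 deg
with a gap of at most 75 ms are merged. Trials are excluded when fewer than
70% of samples are valid or when externally measured calibration drift
exceeds ~1 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from gazeatlas.core import FixationRecord, GazeSample, ScreenGeometry, ValidationError
from gazeatlas.geometry import px_per_degree

__all__ = [
    "IVTParams",
    "TrialQCReport",
    "classify_fixations_ivt",
    "merge_adjacent_fixations",
    "qc_trial",
]


@dataclass(frozen=True)
class IVTParams:
    """Tunables of the I-VT classifier and the fixation-merge pass.

    Defaults: 30 deg/s velocity threshold, 60 ms minimum fixation (the low
    end of the conventional 60-80 ms band), merge window 0.5 deg / 75 ms.
    """

    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: float = 60.0
    merge_max_gap_ms: float = 75.0
    merge_max_dist_deg: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "velocity_threshold_deg_s",
            "min_fixation_ms",
            "merge_max_gap_ms",
            "merge_max_dist_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TrialQCReport:
    participant_id: str
    ad_id: str
    valid_fraction: float
    drift_deg: Optional[float]
    excluded: bool
    reason: str  # valid_below_threshold | drift_exceeded | disengaged | none


def _check_single_trial(samples: Sequence[GazeSample]) -> tuple[str, str]:
    keys = {(s.participant_id, s.ad_id) for s in samples}
    if len(keys) != 1:
        raise ValidationError(f"samples span multiple (participant, ad) trials: {sorted(keys)}")
    return next(iter(keys))


def classify_fixations_ivt(
    samples: Sequence[GazeSample],
    params: IVTParams | None = None,
    geometry: ScreenGeometry | None = None,
) -> list[FixationRecord]:
    """Segment one trial's gaze samples into fixations with I-VT.

    Velocity at each sample is the two-point backward difference to the
    previous valid sample (the first valid sample inherits the velocity of
    its successor). Invalid samples break runs. A run of below-threshold
    samples becomes a fixation when its time span (last minus first
    timestamp) reaches the minimum fixation duration; its centroid is the
    mean of member coordinates.

    Fewer than two valid samples yield an empty result; non-monotone
    timestamps are an error.
    """
    params = params or IVTParams()
    geometry = geometry or ScreenGeometry()
    if not samples:
        return []
    participant_id, ad_id = _check_single_trial(samples)
    times = [s.t_ms for s in samples]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("gaze timestamps must be strictly increasing")

    valid = [s for s in samples if s.valid]
    if len(valid) < 2:
        return []
    ppd = px_per_degree(geometry)

    # Velocity per sample (deg/s); None for invalid samples.
    velocities: list[Optional[float]] = [None] * len(samples)
    prev_valid_idx: Optional[int] = None
    first_valid_idx: Optional[int] = None
    for i, s in enumerate(samples):
        if not s.valid:
            prev_valid_idx = None  # invalid sample breaks the chain
            continue
        if prev_valid_idx is None:
            if first_valid_idx is None:
                first_valid_idx = i
            prev_valid_idx = i
            continue
        p = samples[prev_valid_idx]
        dt_s = (s.t_ms - p.t_ms) / 1000.0
        dist_deg = math.hypot(s.x_px - p.x_px, s.y_px - p.y_px) / ppd
        velocities[i] = dist_deg / dt_s
        if velocities[prev_valid_idx] is None:
            # leading sample of a valid chain inherits its successor's velocity
            velocities[prev_valid_idx] = velocities[i]
        prev_valid_idx = i

    fixational = [
        s.valid and velocities[i] is not None
        and velocities[i] < params.velocity_threshold_deg_s
        for i, s in enumerate(samples)
    ]

    fixations: list[FixationRecord] = []
    run: list[GazeSample] = []

    def flush() -> None:
        if not run:
            return
        duration = run[-1].t_ms - run[0].t_ms
        if duration >= params.min_fixation_ms:
            fixations.append(
                FixationRecord(
                    participant_id=participant_id,
                    ad_id=ad_id,
                    onset_ms=run[0].t_ms,
                    duration_ms=duration,
                    cx_px=sum(s.x_px for s in run) / len(run),
                    cy_px=sum(s.y_px for s in run) / len(run),
                )
            )
        run.clear()

    for i, s in enumerate(samples):
        if fixational[i]:
            run.append(s)
        else:
            flush()
    flush()
    return fixations


def merge_adjacent_fixations(
    fixations: Sequence[FixationRecord],
    params: IVTParams | None = None,
    geometry: ScreenGeometry | None = None,
) -> list[FixationRecord]:
    """Merge consecutive fixations within 0.5 deg and <= 75 ms of each other.

    Merging is applied left-to-right until stable. The merged fixation spans
    first onset to last offset; its centroid is the duration-weighted mean
    of the members' centroids (preserving dwell mass).
    """
    params = params or IVTParams()
    geometry = geometry or ScreenGeometry()
    ppd = px_per_degree(geometry)
    out = [FixationRecord(**vars(f)) for f in fixations]

    changed = True
    while changed:
        changed = False
        merged: list[FixationRecord] = []
        for f in out:
            if merged:
                prev = merged[-1]
                gap = f.onset_ms - prev.offset_ms
                dist_deg = math.hypot(f.cx_px - prev.cx_px, f.cy_px - prev.cy_px) / ppd
                if gap <= params.merge_max_gap_ms and dist_deg <= params.merge_max_dist_deg:
                    w1, w2 = prev.duration_ms, f.duration_ms
                    total_w = w1 + w2 if (w1 + w2) > 0 else 1.0
                    merged[-1] = FixationRecord(
                        participant_id=prev.participant_id,
                        ad_id=prev.ad_id,
                        onset_ms=prev.onset_ms,
                        duration_ms=f.offset_ms - prev.onset_ms,
                        cx_px=(prev.cx_px * w1 + f.cx_px * w2) / total_w,
                        cy_px=(prev.cy_px * w1 + f.cy_px * w2) / total_w,
                        aoi_id=prev.aoi_id,
                    )
                    changed = True
                    continue
            merged.append(f)
        out = merged
    return out


def qc_trial(
    samples: Sequence[GazeSample],
    drift_deg: Optional[float] = None,
    valid_threshold: float = 0.70,
    drift_threshold_deg: float = 1.0,
) -> TrialQCReport:
    """Trial-level quality control on valid-sample share and drift.

    The drift scalar comes from external validation screens (it is not
    estimated from the stimulus stream). An empty trial is excluded as
    disengaged.
    """
    if not samples:
        return TrialQCReport(
            participant_id="",
            ad_id="",
            valid_fraction=0.0,
            drift_deg=drift_deg,
            excluded=True,
            reason="disengaged",
        )
    participant_id, ad_id = _check_single_trial(samples)
    n_valid = sum(1 for s in samples if s.valid)
    frac = n_valid / len(samples)
    if n_valid == 0:
        reason = "disengaged"
    elif frac < valid_threshold:
        reason = "valid_below_threshold"
    elif drift_deg is not None and drift_deg > drift_threshold_deg:
        reason = "drift_exceeded"
    else:
        reason = "none"
    return TrialQCReport(
        participant_id=participant_id,
        ad_id=ad_id,
        valid_fraction=frac,
        drift_deg=drift_deg,
        excluded=reason != "none",
        reason=reason,
    )
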