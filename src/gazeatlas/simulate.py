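"""Synthetic gaze-study generator with analytic ground truth.

The generator emulates a lab study in which each participant views a set of
static ads for a fixed exposure while a screen-based eye tracker samples
gaze at 60 Hz. Per trial it draws, from configured per-AOI models,

* the entry AOI (first hit) from a salience-weight multinomial,
* which other AOIs are fixated at all (per-AOI skip probability, i.e.
  censoring),
* log-normal first-fixation latencies (the entry AOI receives the smallest
  draw, so the configured entry weights are the true first-hit
  distribution),
* gamma-distributed total dwell per fixated AOI, apportioned across one or
  more fixations,

and then lays the fixations on a timeline (drawn latencies honored when
the timeline allows, otherwise pushed after the previous fixation plus a
saccade gap) inside the AOI polygons. Gaze samples are synthesized from the
fixation timeline: near-stationary jittered samples during fixations,
invalid (blink-like) samples during inter-fixation gaps, and fast valid
scanning sweeps outside the fixation span. The long-form study table is
derived from the emitted fixations, so metrics recomputed from the
fixations reproduce the table exactly.

Stratum modifiers multiply entry weights and dwell scale per semantic
category, letting tests verify that subgroup analyses recover configured
audience shifts. Ground-truth pairwise win probabilities are computed from
the configured dwell distributions by numerical integration.

Seeding uses one root seed with counter-derived substreams per participant
and trial, so enlarging the panel never perturbs earlier participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import integrate, stats

from gazeatlas.core import (
    AttentionRecord,
    Category,
    FixationRecord,
    GazeSample,
    ScreenGeometry,
    StudyTable,
    ValidationError,
    normalize_category,
)
from gazeatlas.geometry import AOIDefinition

__all__ = [
    "DwellModel",
    "TTFFModel",
    "AOISpec",
    "StratumModifier",
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "GroundTruth",
    "generate_study",
    "ground_truth_matrix",
    "ground_truth_first_hit",
    "ground_truth_category_order",
    "default_study_config",
    "small_study_config",
]

_SACCADE_GAP_MS = 100.0  # inter-fixation gap; > merge window so visits stay distinct
_MIN_DWELL_MS = 120.0  # floor on per-AOI dwell; keeps every visit >= one fixation
_MIN_FIX_MS = 60.0


@dataclass(frozen=True)
class DwellModel:
    """Total-dwell distribution for one AOI.

    ``gamma`` uses shape/scale (mean = shape * scale, right-skewed like real
    dwell); ``fixed`` is a point mass, useful for constructing exact ties.
    """

    kind: Literal["gamma", "fixed"] = "gamma"
    shape: float = 3.0
    scale_ms: float = 150.0
    value_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.kind == "gamma" and (self.shape <= 0 or self.scale_ms <= 0):
            raise ValidationError("gamma dwell parameters must be positive")
        if self.kind == "fixed" and self.value_ms <= 0:
            raise ValidationError("fixed dwell value must be positive")

    @property
    def mean_ms(self) -> float:
        return self.shape * self.scale_ms if self.kind == "gamma" else self.value_ms

    def frozen(self, dwell_multiplier: float = 1.0):
        if self.kind == "gamma":
            return stats.gamma(self.shape, scale=self.scale_ms * dwell_multiplier)
        return None  # point mass handled separately


@dataclass(frozen=True)
class TTFFModel:
    """Log-normal first-fixation latency: median (ms) and log-space spread."""

    median_ms: float = 800.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.median_ms <= 0 or self.sigma <= 0:
            raise ValidationError("TTFF parameters must be positive")


@dataclass(frozen=True)
class AOISpec:
    """Generative model of one AOI: geometry plus attention parameters."""

    aoi_id: str
    category: Category
    vertices: tuple[tuple[float, float], ...]
    entry_weight: float = 1.0
    ttff: TTFFModel = field(default_factory=TTFFModel)
    dwell: DwellModel = field(default_factory=DwellModel)
    p_skip: float = 0.2

    def __post_init__(self) -> None:
        if self.entry_weight < 0:
            raise ValidationError("entry_weight must be non-negative")
        if not (0 <= self.p_skip < 1):
            raise ValidationError("p_skip must lie in [0, 1)")


@dataclass(frozen=True)
class StratumModifier:
    """Multiplicative shifts applied to participants of one stratum level.

    ``entry`` multiplies entry weights and ``dwell`` multiplies dwell scale
    for AOIs of the named categories.
    """

    entry: Mapping[Category, float] = field(default_factory=dict)
    dwell: Mapping[Category, float] = field(default_factory=dict)


@dataclass
class SyntheticStudyConfig:
    """Full generative specification of a synthetic study."""

    ads: dict[str, list[AOISpec]]
    n_participants: int = 30
    strata_levels: dict[str, list[str]] = field(default_factory=dict)
    strata_proportions: dict[str, list[float]] = field(default_factory=dict)
    subgroup_modifiers: dict[str, StratumModifier] = field(default_factory=dict)
    exposure_ms: float = 10_000.0
    censor_ms: float = 10_000.0
    sampling_rate_hz: float = 60.0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not self.ads:
            raise ValidationError("config must define at least one ad")
        for dim, levels in self.strata_levels.items():
            props = self.strata_proportions.get(dim)
            if props is None or len(props) != len(levels):
                raise ValidationError(f"strata_proportions missing/mismatched for {dim!r}")
            if abs(sum(props) - 1.0) > 0.01:
                raise ValidationError(f"strata proportions for {dim!r} must sum to 1")
            total = sum(props)
            self.strata_proportions[dim] = [p / total for p in props]
        max_dwell_mod = 1.0
        for mod in self.subgroup_modifiers.values():
            for v in mod.dwell.values():
                max_dwell_mod = max(max_dwell_mod, v)
        for ad_id, aois in self.ads.items():
            if not aois:
                raise ValidationError(f"ad {ad_id!r} has no AOIs")
            if sum(a.entry_weight for a in aois) <= 0:
                raise ValidationError(f"ad {ad_id!r} entry weights are all zero")
            budget = sum(a.dwell.mean_ms * max_dwell_mod for a in aois)
            budget += _SACCADE_GAP_MS * 2 * len(aois)
            if budget > self.exposure_ms:
                raise ValidationError(
                    f"ad {ad_id!r}: expected total dwell {budget:.0f} ms exceeds the "
                    f"{self.exposure_ms:.0f} ms exposure; reduce dwell means or AOI count"
                )

    def aoi_definitions(self, ad_id: str) -> list[AOIDefinition]:
        return [
            AOIDefinition(
                ad_id=ad_id, aoi_id=a.aoi_id, category=a.category, vertices=list(a.vertices)
            )
            for a in self.ads[ad_id]
        ]


@dataclass
class SyntheticStudy:
    """Everything one generator run emits, in mutually consistent form."""

    samples: list[GazeSample]
    fixations: list[FixationRecord]
    table: StudyTable
    strata: dict[str, dict[str, str]]
    config: SyntheticStudyConfig


@dataclass
class GroundTruth:
    """Analytic truth of a configured ad, for recovery testing."""

    ad_id: str
    first_hit: dict[str, float]  # AOI -> true first-hit percentage
    pairwise: "object"  # PairwiseMatrix (AOI-level)
    category_order: list[str]


# ---------------------------------------------------------------------------
# Generation


def _rng(seed: int, *counters: int) -> np.random.Generator:
    # counter-derived substream: stable under panel growth
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=counters))


def _participant_multipliers(
    config: SyntheticStudyConfig, levels: Mapping[str, str], aoi: AOISpec
) -> tuple[float, float]:
    entry_mult = dwell_mult = 1.0
    for level in levels.values():
        mod = config.subgroup_modifiers.get(level)
        if mod is None:
            continue
        entry_mult *= mod.entry.get(aoi.category, 1.0)
        dwell_mult *= mod.dwell.get(aoi.category, 1.0)
    return entry_mult, dwell_mult


def _anchor_point(aoi: AOISpec) -> tuple[float, float]:
    from shapely.geometry import Polygon

    p = Polygon(aoi.vertices).representative_point()
    return (p.x, p.y)


def _draw_dwell(aoi: AOISpec, dwell_mult: float, rng: np.random.Generator) -> float:
    if aoi.dwell.kind == "fixed":
        return aoi.dwell.value_ms * dwell_mult
    raw = rng.gamma(aoi.dwell.shape, aoi.dwell.scale_ms * dwell_mult)
    return max(raw, _MIN_DWELL_MS)


def _split_dwell(dwell: float, rng: np.random.Generator) -> list[float]:
    """Apportion an AOI's dwell over >= 1 fixations, each >= the minimum."""
    target = 1 + rng.poisson(dwell / 600.0)
    n = int(max(1, min(target, math.floor(dwell / _MIN_FIX_MS))))
    if n == 1:
        return [dwell]
    extra = dwell - _MIN_FIX_MS * n
    shares = rng.dirichlet(np.full(n, 2.0))
    return list(_MIN_FIX_MS + extra * shares)


def _generate_trial(
    config: SyntheticStudyConfig,
    participant_id: str,
    levels: Mapping[str, str],
    ad_id: str,
    rng: np.random.Generator,
    anchors: Mapping[str, tuple[float, float]],
) -> list[FixationRecord]:
    aois = config.ads[ad_id]
    weights = np.array(
        [a.entry_weight * _participant_multipliers(config, levels, a)[0] for a in aois]
    )
    entry_idx = int(rng.choice(len(aois), p=weights / weights.sum()))

    fixated = [
        i == entry_idx or rng.random() >= aois[i].p_skip for i in range(len(aois))
    ]
    idx_fix = [i for i, f in enumerate(fixated) if f]

    latencies = np.array(
        [
            rng.lognormal(math.log(aois[i].ttff.median_ms), aois[i].ttff.sigma)
            for i in idx_fix
        ]
    )
    # hand the smallest latency to the entry AOI, keep the rest in draw order
    order = np.argsort(latencies, kind="stable")
    lat = dict(zip(idx_fix, latencies))
    min_i = idx_fix[int(order[0])]
    if min_i != entry_idx:
        lat[min_i], lat[entry_idx] = lat[entry_idx], lat[min_i]

    dwell = {
        i: _draw_dwell(aois[i], _participant_multipliers(config, levels, aois[i])[1], rng)
        for i in idx_fix
    }
    # point-mass dwell stays a single fixation so equal values yield exact
    # ties in the table (splitting would perturb totals by float error)
    visits = {
        i: [dwell[i]] if aois[i].dwell.kind == "fixed" else _split_dwell(dwell[i], rng)
        for i in idx_fix
    }

    # schedule: first visits in latency order, then remaining visits interleaved
    first_order = sorted(idx_fix, key=lambda i: lat[i])
    events: list[tuple[int, float, Optional[float]]] = [
        (i, visits[i][0], lat[i]) for i in first_order
    ]
    revisit_pool = [(i, d) for i in first_order for d in visits[i][1:]]
    rng.shuffle(revisit_pool)
    events += [(i, d, None) for i, d in revisit_pool]

    def layout(durations: list[float]) -> list[tuple[int, float, float]]:
        placed = []
        t = 0.0
        for (i, _, want), dur in zip(events, durations):
            onset = max(want, t) if want is not None else t
            placed.append((i, onset, dur))
            t = onset + dur + _SACCADE_GAP_MS
        return placed

    durations = [d for _, d, _ in events]
    placed = layout(durations)
    end = placed[-1][1] + placed[-1][2]
    if end > config.exposure_ms:
        # proportional rescale of every AOI's total dwell preserves dwell
        # order across AOIs, so pairwise comparisons (and ground-truth P)
        # are unaffected; each total is then re-apportioned so every
        # surviving fixation keeps the minimum duration
        overhead = end - sum(durations)
        factor = max(0.05, (config.exposure_ms - overhead) / sum(durations))
        new_visits = {}
        for i in idx_fix:
            total = max(sum(visits[i]) * factor, float(_MIN_FIX_MS))
            n = int(max(1, min(len(visits[i]), math.floor(total / _MIN_FIX_MS))))
            kept = visits[i][:n]
            extra = total - _MIN_FIX_MS * n
            w = np.asarray(kept) / sum(kept)
            new_visits[i] = [_MIN_FIX_MS + extra * float(s) for s in w]
        cursor = {i: 0 for i in idx_fix}
        new_events = []
        for i, _, want in events:
            k = cursor[i]
            if k < len(new_visits[i]):
                new_events.append((i, new_visits[i][k], want))
                cursor[i] = k + 1
        events = new_events
        durations = [d for _, d, _ in events]
        placed = layout(durations)
        # drop anything that still spills past the exposure
        placed = [(i, on, du) for i, on, du in placed if on + du <= config.exposure_ms]

    out: list[FixationRecord] = []
    for i, onset, dur in placed:
        x0, y0 = anchors[aois[i].aoi_id]
        out.append(
            FixationRecord(
                participant_id=participant_id,
                ad_id=ad_id,
                onset_ms=onset,
                duration_ms=dur,
                cx_px=x0,
                cy_px=y0,
                aoi_id=aois[i].aoi_id,
            )
        )
    return out


def _synthesize_samples(
    config: SyntheticStudyConfig,
    participant_id: str,
    ad_id: str,
    fixations: Sequence[FixationRecord],
    rng: np.random.Generator,
) -> list[GazeSample]:
    """Sample the fixation timeline at the tracker rate.

    Fixation intervals yield valid, lightly jittered samples; gaps between
    fixations yield invalid (blink-like) samples; leading/trailing segments
    yield valid high-velocity sweeps between two distant anchors so they
    never classify as fixations.
    """
    dt = 1000.0 / config.sampling_rate_hz
    n = int(config.exposure_ms / dt)
    g = config.geometry
    sweep = [(g.width_px * 0.2, g.height_px * 0.85), (g.width_px * 0.8, g.height_px * 0.1)]
    fx = sorted(fixations, key=lambda f: f.onset_ms)
    samples: list[GazeSample] = []
    for k in range(n):
        t = k * dt
        current = next((f for f in fx if f.onset_ms <= t <= f.offset_ms), None)
        if current is not None:
            jx, jy = rng.normal(0.0, 1.0, size=2)
            samples.append(
                GazeSample(participant_id, ad_id, t, current.cx_px + jx, current.cy_px + jy, True)
            )
            continue
        in_gap = any(
            f1.offset_ms < t < f2.onset_ms for f1, f2 in zip(fx, fx[1:])
        )
        if in_gap:
            samples.append(GazeSample(participant_id, ad_id, t, math.nan, math.nan, False))
        else:
            x, y = sweep[k % 2]
            samples.append(GazeSample(participant_id, ad_id, t, x, y, True))
    return samples


def generate_study(config: SyntheticStudyConfig, emit_gaze: bool = True) -> SyntheticStudy:
    """Generate a full synthetic study, deterministic given the config seed.

    Returns mutually consistent gaze samples, fixations, long-form study
    table (derived from the fixations), and a participant -> strata map.
    Set ``emit_gaze=False`` to skip raw-sample synthesis for large recovery
    simulations that only need the table.
    """
    strata: dict[str, dict[str, str]] = {}
    fixations: list[FixationRecord] = []
    samples: list[GazeSample] = []
    records: list[AttentionRecord] = []
    ad_ids = sorted(config.ads)
    anchors = {
        ad_id: {a.aoi_id: _anchor_point(a) for a in config.ads[ad_id]} for ad_id in ad_ids
    }
    width = max(2, len(str(config.n_participants)))
    for p_idx in range(config.n_participants):
        participant_id = f"P{p_idx + 1:0{width}d}"
        rng_strata = _rng(config.seed, p_idx, 0)
        levels = {}
        for dim in sorted(config.strata_levels):
            opts = config.strata_levels[dim]
            props = np.asarray(config.strata_proportions[dim], dtype=float)
            levels[dim] = str(rng_strata.choice(opts, p=props / props.sum()))
        strata[participant_id] = levels

        for ad_idx, ad_id in enumerate(ad_ids):
            rng = _rng(config.seed, p_idx, 1 + ad_idx)
            trial = _generate_trial(config, participant_id, levels, ad_id, rng, anchors[ad_id])
            fixations.extend(trial)
            if emit_gaze:
                samples.extend(
                    _synthesize_samples(config, participant_id, ad_id, trial, rng)
                )
            # derive the long-form rows from the emitted fixations
            per_aoi: dict[str, list[FixationRecord]] = {}
            for f in trial:
                per_aoi.setdefault(f.aoi_id, []).append(f)
            for a in config.ads[ad_id]:
                hits = per_aoi.get(a.aoi_id, [])
                if hits:
                    records.append(
                        AttentionRecord(
                            participant_id=participant_id,
                            ad_id=ad_id,
                            aoi_id=a.aoi_id,
                            category=a.category,
                            ttff_ms=min(h.onset_ms for h in hits),
                            censored=False,
                            fc=len(hits),
                            fd_ms=sum(h.duration_ms for h in hits),
                            **levels_kw(levels),
                        )
                    )
                else:
                    records.append(
                        AttentionRecord(
                            participant_id=participant_id,
                            ad_id=ad_id,
                            aoi_id=a.aoi_id,
                            category=a.category,
                            ttff_ms=config.censor_ms,
                            censored=True,
                            fc=0,
                            fd_ms=0.0,
                            **levels_kw(levels),
                        )
                    )
    table = StudyTable(
        records=records,
        geometry=config.geometry,
        exposure_ms=config.exposure_ms,
        censor_ms=config.censor_ms,
    )
    return SyntheticStudy(
        samples=samples, fixations=fixations, table=table, strata=strata, config=config
    )


def levels_kw(levels: Mapping[str, str]) -> dict[str, str]:
    return {
        "age_band": levels.get("age_band", ""),
        "household": levels.get("household", ""),
        "education": levels.get("education", ""),
    }


# ---------------------------------------------------------------------------
# Ground truth


def _strata_combos(config: SyntheticStudyConfig):
    """Iterate (joint probability, levels dict) over all stratum combinations."""
    dims = sorted(config.strata_levels)
    if not dims:
        yield 1.0, {}
        return

    def rec(i: int, prob: float, levels: dict[str, str]):
        if i == len(dims):
            yield prob, dict(levels)
            return
        dim = dims[i]
        for lvl, p in zip(config.strata_levels[dim], config.strata_proportions[dim]):
            levels[dim] = lvl
            yield from rec(i + 1, prob * p, levels)
        del levels[dim]

    yield from rec(0, 1.0, {})


def _win_probability(
    a: AOISpec, b: AOISpec, mult_a: float, mult_b: float
) -> float:
    """Pr[dwell_a > dwell_b] + 0.5 Pr[equal], from the configured models."""
    da, db = a.dwell, b.dwell
    if da.kind == "fixed" and db.kind == "fixed":
        va, vb = da.value_ms * mult_a, db.value_ms * mult_b
        return 1.0 if va > vb else 0.5 if va == vb else 0.0
    if da.kind == "fixed":
        return float(db.frozen(mult_b).cdf(da.value_ms * mult_a))
    if db.kind == "fixed":
        return float(da.frozen(mult_a).sf(db.value_ms * mult_b))
    fa, fb = da.frozen(mult_a), db.frozen(mult_b)
    upper = max(fa.ppf(1 - 1e-10), fb.ppf(1 - 1e-10))
    val, _ = integrate.quad(lambda x: fa.pdf(x) * fb.cdf(x), 0.0, upper, limit=200)
    return float(min(1.0, max(0.0, val)))


def ground_truth_matrix(config: SyntheticStudyConfig, ad_id: str):
    """True AOI-level pairwise win-probability matrix for one configured ad.

    P_ij = Pr[dwell_i > dwell_j] (+ half the tie mass for point-mass
    models), integrated numerically over the dwell distributions and
    averaged over the stratum mixture. Satisfies the construction axioms
    exactly.
    """
    from gazeatlas.dominance import PairwiseMatrix

    aois = sorted(config.ads[ad_id], key=lambda a: a.aoi_id)
    combos = list(_strata_combos(config))
    k = len(aois)
    P = np.full((k, k), 0.5)
    for i in range(k):
        for j in range(i + 1, k):
            p = 0.0
            for prob, levels in combos:
                mi = _participant_multipliers(config, levels, aois[i])[1]
                mj = _participant_multipliers(config, levels, aois[j])[1]
                p += prob * _win_probability(aois[i], aois[j], mi, mj)
            P[i, j] = p
            P[j, i] = 1.0 - p
    N = np.zeros((k, k), dtype=int)
    return PairwiseMatrix(
        ad_id=ad_id, keys=[a.aoi_id for a in aois], P=P, N=N, kind="dwell"
    )


def ground_truth_first_hit(
    config: SyntheticStudyConfig, ad_id: str, level: str = "aoi"
) -> dict[str, float]:
    """True first-hit distribution (percent) implied by the entry weights,
    averaged over the stratum mixture of entry modifiers."""
    aois = config.ads[ad_id]
    acc = np.zeros(len(aois))
    for prob, levels in _strata_combos(config):
        w = np.array(
            [a.entry_weight * _participant_multipliers(config, levels, a)[0] for a in aois]
        )
        acc += prob * w / w.sum()
    pct = 100.0 * acc / acc.sum()
    if level == "aoi":
        return {a.aoi_id: float(p) for a, p in zip(aois, pct)}
    out: dict[str, float] = {}
    for a, p in zip(aois, pct):
        out[a.category.value] = out.get(a.category.value, 0.0) + float(p)
    return out


def ground_truth_category_order(
    config: SyntheticStudyConfig, ad_id: str, n_mc: int = 20_000
) -> list[str]:
    """True category dominance order, by Monte-Carlo on the configured
    dwell models (category dwell is a censored sum of AOI dwells, which has
    no convenient closed form)."""
    from gazeatlas.dominance import dominance_scores, pairwise_dwell_matrix

    aois = config.ads[ad_id]
    rng = _rng(config.seed, 999_983, 0)
    records: list[AttentionRecord] = []
    combos = list(_strata_combos(config))
    probs = np.array([p for p, _ in combos])
    for p_idx in range(n_mc):
        levels = combos[int(rng.choice(len(combos), p=probs))][1]
        pid = f"M{p_idx}"
        for a in aois:
            if rng.random() < a.p_skip:
                continue
            mult = _participant_multipliers(config, levels, a)[1]
            records.append(
                AttentionRecord(
                    participant_id=pid,
                    ad_id=ad_id,
                    aoi_id=a.aoi_id,
                    category=a.category,
                    ttff_ms=0.0,
                    censored=False,
                    fc=1,
                    fd_ms=_draw_dwell(a, mult, rng),
                )
            )
    matrix = pairwise_dwell_matrix(records, level="category")
    ranking = dominance_scores(matrix)
    return ranking.ordered_keys()


# ---------------------------------------------------------------------------
# Default configurations


def _rect(x: float, y: float, w: float, h: float) -> tuple[tuple[float, float], ...]:
    return ((x, y), (x + w, y), (x + w, y + h), (x, y + h))


def _aoi(
    ad: str,
    name: str,
    cat: str,
    rect: tuple,
    entry: float,
    ttff_median: float,
    dwell_mean: float,
    p_skip: float,
    dwell_shape: float = 3.0,
) -> AOISpec:
    return AOISpec(
        aoi_id=name,
        category=normalize_category(cat),
        vertices=_rect(*rect),
        entry_weight=entry,
        ttff=TTFFModel(median_ms=ttff_median, sigma=0.6),
        dwell=DwellModel(kind="gamma", shape=dwell_shape, scale_ms=dwell_mean / dwell_shape),
        p_skip=p_skip,
    )


def default_study_config(seed: int = 0) -> SyntheticStudyConfig:
    """The study-scale default: 30 participants, 6 ads, 41 AOIs across six
    semantic categories, 10 s exposures at 60 Hz, stratified by four age
    bands, four household types, and four education levels.

    Entry weights and dwell means are chosen so that symbol/image-forward
    creatives attract first fixations to visuals while text- and
    source-forward creatives route entry to copy and endorsers, with
    message-carrying elements tending to win dwell; peripheral elements
    carry higher skip probabilities. Per-ad expected dwell stays within the
    exposure.
    """
    ads: dict[str, list[AOISpec]] = {
        # 4 AOIs: symbol-forward creative
        "Ad1": [
            _aoi("Ad1", "WomansFace", "Image", (700, 200, 500, 400), 3.0, 600, 1300, 0.05),
            _aoi("Ad1", "Icon(ribbon)", "Symbol", (150, 150, 250, 250), 6.0, 400, 1100, 0.05),
            _aoi("Ad1", "HeadText", "Text", (200, 700, 900, 180), 1.0, 1500, 900, 0.15),
            _aoi("Ad1", "Icon(heart)", "Symbol", (1500, 800, 200, 200), 0.5, 2500, 700, 0.35),
        ],
        # 8 AOIs: source/copy-forward creative
        "Ad2": [
            _aoi("Ad2", "Text", "Text", (150, 400, 800, 300), 3.5, 700, 1400, 0.05),
            _aoi("Ad2", "FofiGenimata", "Source/Authority", (1100, 150, 400, 450), 5.0, 500, 1000, 0.10),
            _aoi("Ad2", "Icon(heart)", "Symbol", (300, 120, 180, 180), 0.7, 1800, 900, 0.25),
            _aoi("Ad2", "HeadText", "Text", (150, 80, 700, 150), 0.6, 1200, 600, 0.20),
            _aoi("Ad2", "Family", "Image", (1050, 650, 500, 350), 0.7, 2200, 500, 0.30),
            _aoi("Ad2", "Icon(breasts)", "Symbol", (700, 850, 160, 160), 0.2, 3000, 350, 0.45),
            _aoi("Ad2", "Kivernisi", "Source/Authority", (80, 950, 350, 100), 0.2, 3500, 400, 0.40),
            _aoi("Ad2", "SmallText", "Text", (900, 950, 400, 90), 0.1, 4000, 300, 0.50),
        ],
        # 10 AOIs: infographic creative
        "Ad3": [
            _aoi("Ad3", "Icon1Statistics", "Symbol", (150, 200, 260, 260), 2.5, 700, 650, 0.15),
            _aoi("Ad3", "Icon2Statistics", "Symbol", (550, 200, 260, 260), 2.0, 900, 600, 0.20),
            _aoi("Ad3", "Icon3Statistics", "Symbol", (950, 200, 260, 260), 1.5, 1100, 500, 0.25),
            _aoi("Ad3", "HeadText", "Text", (150, 60, 1100, 120), 2.5, 800, 850, 0.10),
            _aoi("Ad3", "SmallText1", "Text", (150, 520, 380, 140), 0.6, 2000, 450, 0.30),
            _aoi("Ad3", "SmallText2", "Text", (550, 520, 380, 140), 0.4, 2500, 400, 0.35),
            _aoi("Ad3", "SmallText3", "Text", (950, 520, 380, 140), 0.2, 3000, 300, 0.45),
            _aoi("Ad3", "BusinessWebsite(Ygeia)", "Website", (1450, 900, 380, 110), 0.3, 2500, 900, 0.30),
            _aoi("Ad3", "BusinessLogo(Ygeia)", "Logo", (1450, 120, 330, 200), 1.2, 600, 850, 0.25),
            _aoi("Ad3", "Icon(ribbon)", "Symbol", (80, 850, 170, 170), 0.3, 3200, 350, 0.40),
        ],
        # 6 AOIs: picture + long copy creative
        "Ad4": [
            _aoi("Ad4", "Picture(womanhand-drawn)", "Image", (1000, 250, 700, 600), 3.0, 700, 1300, 0.05),
            _aoi("Ad4", "HeadText", "Text", (120, 100, 800, 160), 1.5, 1000, 700, 0.15),
            _aoi("Ad4", "Text", "Text", (120, 350, 750, 450), 1.7, 1200, 1700, 0.05),
            _aoi("Ad4", "Icon(breast)", "Symbol", (450, 870, 200, 200), 2.0, 1500, 800, 0.25),
            _aoi("Ad4", "BusinessWebsite(AlphaBank)", "Website", (1150, 950, 450, 100), 2.3, 900, 500, 0.30),
            _aoi("Ad4", "BusinessLogo(AlphaBank)", "Logo", (1650, 60, 220, 160), 1.0, 1400, 700, 0.30),
        ],
        # 5 AOIs: image-forward creative
        "Ad5": [
            _aoi("Ad5", "Picture(magnifier/breasts)", "Image", (650, 250, 650, 550), 3.7, 500, 1400, 0.05),
            _aoi("Ad5", "HeadText", "Text", (150, 80, 900, 150), 1.3, 1000, 750, 0.15),
            _aoi("Ad5", "Text", "Text", (150, 450, 420, 400), 1.7, 1300, 1350, 0.10),
            _aoi("Ad5", "BusinessWebsite(ProtoTheme)", "Website", (1400, 950, 420, 100), 1.3, 1800, 550, 0.35),
            _aoi("Ad5", "BusinessLogo(ProtoThema)", "Logo", (1550, 80, 300, 180), 1.7, 1100, 650, 0.30),
        ],
        # 8 AOIs: authority-forward creative
        "Ad6": [
            _aoi("Ad6", "Headtext", "Text", (150, 80, 900, 150), 1.2, 1100, 650, 0.15),
            _aoi("Ad6", "Icon(ribbon)", "Symbol", (1200, 100, 200, 200), 2.5, 900, 450, 0.25),
            _aoi("Ad6", "picture(fist)", "Image", (700, 350, 500, 450), 0.6, 1700, 650, 0.20),
            _aoi("Ad6", "IconswithText", "Text", (120, 350, 480, 400), 1.2, 1500, 1050, 0.15),
            _aoi("Ad6", "Website", "Website", (1350, 950, 450, 100), 1.3, 1600, 900, 0.30),
            _aoi("Ad6", "FofiGenimata", "Source/Authority", (1400, 350, 400, 450), 2.0, 800, 800, 0.15),
            _aoi("Ad6", "YpourgioYgeias", "Source/Authority", (120, 900, 350, 140), 1.2, 1900, 650, 0.30),
            _aoi("Ad6", "Kivernisi", "Source/Authority", (550, 900, 350, 140), 2.0, 1000, 1150, 0.15),
        ],
    }
    strata_levels = {
        "age_band": ["40-45", "46-50", "51-55", "56-60"],
        "household": [
            "Married w/Kids",
            "Married w/o Kids",
            "Single w/Kids",
            "Single w/o Kids",
        ],
        "education": ["Primary", "Compulsory/HS", "University", "Masters+"],
    }
    strata_proportions = {
        "age_band": [0.30, 0.167, 0.233, 0.30],
        "household": [0.633, 0.10, 0.10, 0.167],
        "education": [0.133, 0.433, 0.233, 0.20],
    }
    subgroup_modifiers = {
        # older viewers enter on authority cues; younger on symbols/images
        "56-60": StratumModifier(entry={Category.SOURCE_AUTHORITY: 2.0}),
        "40-45": StratumModifier(entry={Category.SYMBOL: 1.5, Category.IMAGE_VISUAL: 1.3}),
        # family households orient to endorsers/family imagery
        "Married w/Kids": StratumModifier(entry={Category.SOURCE_AUTHORITY: 1.4}),
        "Single w/o Kids": StratumModifier(entry={Category.SYMBOL: 1.4}),
        # higher education routes entry to copy and CTA, and deepens text dwell
        "University": StratumModifier(
            entry={Category.TEXT: 1.8, Category.WEBSITE_CTA: 1.5},
            dwell={Category.TEXT: 1.2},
        ),
        "Masters+": StratumModifier(
            entry={Category.TEXT: 1.8, Category.WEBSITE_CTA: 1.5},
            dwell={Category.TEXT: 1.2},
        ),
    }
    return SyntheticStudyConfig(
        ads=ads,
        n_participants=30,
        strata_levels=strata_levels,
        strata_proportions=strata_proportions,
        subgroup_modifiers=subgroup_modifiers,
        seed=seed,
    )


def small_study_config(
    seed: int = 0,
    n_participants: int = 10,
    n_aois: int = 4,
    dwell_means: Sequence[float] | None = None,
    entry_weights: Sequence[float] | None = None,
    p_skip: float = 0.0,
) -> SyntheticStudyConfig:
    """A single-ad desk-scale configuration for quick checks and examples."""
    cats = ["Image", "Text", "Symbol", "Logo", "Website", "Source/Authority"]
    dwell_means = list(dwell_means or [1000.0 - 150.0 * i for i in range(n_aois)])
    entry_weights = list(entry_weights or [1.0] * n_aois)
    aois = [
        _aoi(
            "Ad1",
            f"AOI{i + 1}",
            cats[i % len(cats)],
            (100 + 300 * (i % 5), 100 + 350 * (i // 5), 220, 220),
            entry_weights[i],
            500 + 300 * i,
            dwell_means[i],
            p_skip,
        )
        for i in range(n_aois)
    ]
    return SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=n_participants, seed=seed)
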