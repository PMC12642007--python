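"""Synthetic study generator: determinism, ground-truth oracles, and
statistical recovery of the configured attention structure."""

import math

import numpy as np
import pytest

from gazeatlas.core import Category, ValidationError
from gazeatlas.dominance import (
    category_dominance,
    dominance_scores,
    pairwise_dwell_matrix,
    verify_axioms,
)
from gazeatlas.audience import delta_matrix, stratified_first_hit
from gazeatlas.metrics import first_hit, first_hit_distribution
from gazeatlas.simulate import (
    AOISpec,
    DwellModel,
    StratumModifier,
    SyntheticStudyConfig,
    TTFFModel,
    default_study_config,
    generate_study,
    ground_truth_category_order,
    ground_truth_first_hit,
    ground_truth_matrix,
    small_study_config,
)


def _rect(x, y, w, h):
    return ((x, y), (x + w, y), (x + w, y + h), (x, y + h))


def _spec(aoi_id, cat, x, dwell, entry=1.0, p_skip=0.0):
    return AOISpec(
        aoi_id=aoi_id,
        category=cat,
        vertices=_rect(x, 200, 220, 220),
        entry_weight=entry,
        ttff=TTFFModel(median_ms=600.0, sigma=0.5),
        dwell=dwell,
        p_skip=p_skip,
    )


def _first_hits(table, ad_id="Ad1"):
    per = {}
    for r in table.for_ad(ad_id):
        per.setdefault(r.participant_id, []).append(r)
    return [first_hit(recs) for recs in per.values()]


class TestDeterminism:
    def test_same_seed_same_study(self):
        s1 = generate_study(small_study_config(seed=5), emit_gaze=True)
        s2 = generate_study(small_study_config(seed=5), emit_gaze=True)
        assert s1.table.records == s2.table.records
        assert s1.fixations == s2.fixations
        assert s1.samples == s2.samples
        assert s1.strata == s2.strata

    def test_different_seed_differs(self):
        s1 = generate_study(small_study_config(seed=5), emit_gaze=False)
        s2 = generate_study(small_study_config(seed=6), emit_gaze=False)
        assert s1.table.records != s2.table.records

    def test_substreams_stable_under_panel_growth(self):
        # adding participants must not perturb earlier participants' trials
        small = generate_study(small_study_config(seed=3, n_participants=5),
                               emit_gaze=False)
        large = generate_study(small_study_config(seed=3, n_participants=8),
                               emit_gaze=False)
        kept = {r.participant_id for r in small.table.records}
        subset = [r for r in large.table.records if r.participant_id in kept]
        assert subset == small.table.records


class TestDefaultConfig:
    def test_study_scale_shape(self):
        cfg = default_study_config(seed=1)
        assert cfg.n_participants == 30
        assert len(cfg.ads) == 6
        assert sum(len(a) for a in cfg.ads.values()) == 41
        assert [len(cfg.ads[f"Ad{i}"]) for i in range(1, 7)] == [4, 8, 10, 6, 5, 8]
        assert all(len(v) == 4 for v in cfg.strata_levels.values())
        cats = {a.category for aois in cfg.ads.values() for a in aois}
        assert len(cats) == 6

    def test_generated_table_is_complete(self):
        study = generate_study(default_study_config(seed=1), emit_gaze=False)
        # one record per participant x ad x AOI
        assert len(study.table.records) == 30 * 41
        assert len(study.strata) == 30
        assert all(set(v) == {"age_band", "household", "education"}
                   for v in study.strata.values())


class TestInternalConsistency:
    def test_table_matches_fixations(self):
        study = generate_study(small_study_config(seed=2, n_participants=6),
                               emit_gaze=False)
        per_trial = {}
        for f in study.fixations:
            per_trial.setdefault((f.participant_id, f.ad_id), []).append(f)
        for r in study.table.records:
            hits = [f for f in per_trial.get((r.participant_id, r.ad_id), [])
                    if f.aoi_id == r.aoi_id]
            if r.censored:
                assert not hits
            else:
                assert r.fc == len(hits)
                assert r.ttff_ms == pytest.approx(min(f.onset_ms for f in hits))
                assert r.fd_ms == pytest.approx(sum(f.duration_ms for f in hits))

    def test_fixations_fit_exposure_without_overlap(self):
        study = generate_study(small_study_config(seed=7), emit_gaze=False)
        per_trial = {}
        for f in study.fixations:
            per_trial.setdefault((f.participant_id, f.ad_id), []).append(f)
        for fx in per_trial.values():
            fx = sorted(fx, key=lambda f: f.onset_ms)
            assert fx[0].onset_ms >= 0
            assert fx[-1].offset_ms <= study.config.exposure_ms + 1e-6
            for a, b in zip(fx, fx[1:]):
                assert b.onset_ms >= a.offset_ms - 1e-6


class TestGroundTruth:
    def _two_aoi_config(self, seed=0):
        aois = [
            _spec("A", Category.TEXT, 100, DwellModel("gamma", 3.0, 330.0)),
            _spec("B", Category.IMAGE_VISUAL, 500, DwellModel("gamma", 3.0, 160.0)),
        ]
        return SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=200, seed=seed)

    def test_matrix_satisfies_axioms_exactly(self):
        gt = ground_truth_matrix(default_study_config(seed=0), "Ad3")
        rep = verify_axioms(gt, tol=1e-12)
        assert rep.passed

    def test_quadrature_matches_independent_monte_carlo(self):
        # cross-oracle: Pr[Gamma(3, 330) > Gamma(3, 160)] by direct sampling
        gt = ground_truth_matrix(self._two_aoi_config(), "Ad1")
        p_quad = gt.P[gt.keys.index("A"), gt.keys.index("B")]
        rng = np.random.default_rng(12345)
        n = 300_000
        a = rng.gamma(3.0, 330.0, size=n)
        b = rng.gamma(3.0, 160.0, size=n)
        p_mc = float(np.mean(a > b))
        assert p_quad == pytest.approx(p_mc, abs=0.005)

    def test_point_mass_tie_is_half(self):
        aois = [
            _spec("A", Category.TEXT, 100, DwellModel(kind="fixed", value_ms=400.0)),
            _spec("B", Category.IMAGE_VISUAL, 500, DwellModel(kind="fixed", value_ms=400.0)),
        ]
        cfg = SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=6, seed=0)
        gt = ground_truth_matrix(cfg, "Ad1")
        assert gt.P[0, 1] == 0.5
        # and the generated data reproduce the tie exactly
        study = generate_study(cfg, emit_gaze=False)
        m = pairwise_dwell_matrix(study.table.for_ad("Ad1"))
        assert m.P[m.keys.index("A"), m.keys.index("B")] == pytest.approx(0.5)

    def test_first_hit_truth_follows_entry_weights(self):
        aois = [
            _spec("A", Category.TEXT, 100, DwellModel(), entry=2.0),
            _spec("B", Category.IMAGE_VISUAL, 500, DwellModel(), entry=1.0),
            _spec("C", Category.SYMBOL, 900, DwellModel(), entry=1.0),
        ]
        cfg = SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=10, seed=0)
        gt = ground_truth_first_hit(cfg, "Ad1")
        assert gt["A"] == pytest.approx(50.0)
        assert gt["B"] == pytest.approx(25.0)
        assert sum(gt.values()) == pytest.approx(100.0)


class TestRecovery:
    def test_pairwise_probability_recovered(self):
        # true P(A beats B) for Gamma(3, 330) vs Gamma(3, 160) is ~0.80;
        # the empirical matrix at n = 200 must land within 3 binomial SEs
        aois = [
            _spec("A", Category.TEXT, 100, DwellModel("gamma", 3.0, 330.0)),
            _spec("B", Category.IMAGE_VISUAL, 500, DwellModel("gamma", 3.0, 160.0)),
        ]
        cfg = SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=200, seed=11)
        gt = ground_truth_matrix(cfg, "Ad1")
        p_true = gt.P[gt.keys.index("A"), gt.keys.index("B")]
        study = generate_study(cfg, emit_gaze=False)
        m = pairwise_dwell_matrix(study.table.for_ad("Ad1"))
        p_hat = m.P[m.keys.index("A"), m.keys.index("B")]
        n = m.N[m.keys.index("A"), m.keys.index("B")]
        assert n == 200  # p_skip = 0: every participant observes both
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) <= 3 * se

    def test_entry_weights_recovered_in_first_hits(self):
        cfg = small_study_config(seed=4, n_participants=1000, n_aois=3,
                                 entry_weights=[2.0, 1.0, 1.0])
        study = generate_study(cfg, emit_gaze=False)
        dist = first_hit_distribution(_first_hits(study.table), level="aoi")
        truth = ground_truth_first_hit(cfg, "Ad1")
        for aoi, p in truth.items():
            se_pp = 100 * math.sqrt((p / 100) * (1 - p / 100) / 1000)
            assert abs(dist.get(aoi, 0.0) - p) <= 3 * se_pp

    def test_category_order_recovered(self):
        aois = [
            _spec("txt", Category.TEXT, 100, DwellModel("gamma", 3.0, 400.0), p_skip=0.1),
            _spec("img", Category.IMAGE_VISUAL, 500, DwellModel("gamma", 3.0, 230.0), p_skip=0.1),
            _spec("sym", Category.SYMBOL, 900, DwellModel("gamma", 3.0, 100.0), p_skip=0.1),
        ]
        cfg = SyntheticStudyConfig(ads={"Ad1": aois}, n_participants=300, seed=8)
        truth = ground_truth_category_order(cfg, "Ad1", n_mc=4000)
        study = generate_study(cfg, emit_gaze=False)
        ranking = dominance_scores(category_dominance(study.table.for_ad("Ad1")))
        assert ranking.ordered_keys() == truth
        assert truth == ["Text", "Image/Visual", "Symbol"]

    def test_subgroup_modifier_shifts_first_hits(self):
        aois = [
            _spec("sym", Category.SYMBOL, 100, DwellModel(), entry=1.0),
            _spec("txt", Category.TEXT, 500, DwellModel(), entry=1.0),
        ]
        cfg = SyntheticStudyConfig(
            ads={"Ad1": aois},
            n_participants=400,
            strata_levels={"age_band": ["young", "old"]},
            strata_proportions={"age_band": [0.5, 0.5]},
            subgroup_modifiers={"young": StratumModifier(entry={Category.SYMBOL: 9.0})},
            seed=13,
        )
        study = generate_study(cfg, emit_gaze=False)
        hits = _first_hits(study.table)
        overall = first_hit_distribution(hits)
        strata = {p: v["age_band"] for p, v in study.strata.items()}
        sub = stratified_first_hit(hits, strata)
        dm = delta_matrix(sub, overall, ad_id="Ad1", dimension="age_band")
        frame = dm.to_frame()
        # the boosted level over-indexes on Symbol; the other under-indexes
        assert frame.loc["Symbol", "young"] > 10.0
        assert frame.loc["Symbol", "old"] < -10.0


class TestValidation:
    def test_infeasible_dwell_budget_rejected(self):
        with pytest.raises(ValidationError, match="exposure"):
            small_study_config(n_aois=3, dwell_means=[6000.0, 6000.0, 6000.0])

    def test_bad_strata_proportions_rejected(self):
        aois = [_spec("A", Category.TEXT, 100, DwellModel()),
                _spec("B", Category.IMAGE_VISUAL, 500, DwellModel())]
        with pytest.raises(ValidationError, match="sum to 1"):
            SyntheticStudyConfig(
                ads={"Ad1": aois},
                strata_levels={"age_band": ["a", "b"]},
                strata_proportions={"age_band": [0.7, 0.7]},
            )

    def test_dwell_minimums_respected(self):
        study = generate_study(small_study_config(seed=9), emit_gaze=False)
        for f in study.fixations:
            assert f.duration_ms >= 60.0 - 1e-9
        for r in study.table.records:
            if not r.censored:
                assert r.fd_ms >= 60.0 - 1e-9
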