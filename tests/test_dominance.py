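"""Tie-aware pairwise dominance: matrices, scores, precedence, masking,
axioms and concordance — with a brute-force double-loop oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeatlas.core import StudyTable, ValidationError
from gazeatlas.dominance import (
    apply_support_mask,
    category_dominance,
    concordance,
    dominance_scores,
    pairwise_dwell_matrix,
    ttff_precedence_matrix,
    verify_axioms,
)
from gazeatlas.metrics import benchmark_table
from tests.conftest import dwell_records, make_record


def _cell(m, a, b):
    return m.P[m.keys.index(a), m.keys.index(b)]


def _support(m, a, b):
    return m.N[m.keys.index(a), m.keys.index(b)]


class TestPairwiseMatrix:
    def test_worked_example_with_tie(self):
        # (500,300) win, (400,400) tie, (200,600) loss -> (1 + 0.5)/3 = 0.5
        recs = dwell_records("Ad1", {
            "P01": {"A": 500.0, "B": 300.0},
            "P02": {"A": 400.0, "B": 400.0},
            "P03": {"A": 200.0, "B": 600.0},
        })
        m = pairwise_dwell_matrix(recs)
        assert _cell(m, "A", "B") == pytest.approx(0.5)
        assert _support(m, "A", "B") == 3

    def test_only_joint_observers_count(self):
        recs = dwell_records("Ad1", {
            "P01": {"A": 500.0, "B": 300.0},
            "P02": {"A": 400.0, "B": None},  # censored on B: excluded from pair
            "P03": {"A": None, "B": 600.0},  # censored on A: excluded from pair
        })
        m = pairwise_dwell_matrix(recs)
        assert _support(m, "A", "B") == 1
        assert _cell(m, "A", "B") == 1.0
        # diagonal support counts observers of the key itself
        assert _support(m, "A", "A") == 2

    def test_no_joint_observers_undefined(self):
        recs = dwell_records("Ad1", {
            "P01": {"A": 500.0, "B": None},
            "P02": {"A": None, "B": 600.0},
        })
        m = pairwise_dwell_matrix(recs)
        assert math.isnan(_cell(m, "A", "B"))
        assert _support(m, "A", "B") == 0

    def test_all_ties_give_half(self):
        recs = dwell_records("Ad1", {
            f"P{i:02d}": {"A": 400.0, "B": 400.0} for i in range(6)
        })
        m = pairwise_dwell_matrix(recs)
        assert _cell(m, "A", "B") == pytest.approx(0.5)

    def test_diagonal_is_half(self):
        recs = dwell_records("Ad1", {"P01": {"A": 1.0, "B": 2.0}})
        m = pairwise_dwell_matrix(recs)
        assert all(m.P[i, i] == 0.5 for i in range(m.size))

    def test_fewer_than_two_keys_rejected(self):
        recs = dwell_records("Ad1", {"P01": {"A": 1.0}})
        with pytest.raises(ValidationError):
            pairwise_dwell_matrix(recs)


class TestScores:
    def test_worked_score_example(self):
        # hand-built matrix via records is awkward; check the formula on a
        # 3-key configuration whose P rows average to 0.75, 0.40, 0.35
        m = pairwise_dwell_matrix(dwell_records("Ad1", {
            "P01": {"A": 3.0, "B": 2.0, "C": 1.0},
            "P02": {"A": 3.0, "B": 1.0, "C": 2.0},
        }))
        # A beats both always: P_AB = P_AC = 1; B vs C splits 0.5
        r = dominance_scores(m)
        assert r.scores["A"] == pytest.approx(2 * (1.0 - 0.5))
        assert r.scores["B"] == pytest.approx(2 * ((0.0 + 0.5) / 2 - 0.5))
        assert r.scores["C"] == pytest.approx(2 * ((0.0 + 0.5) / 2 - 0.5))
        assert sum(r.scores.values()) == pytest.approx(0.0)
        assert r.ranks["A"] == 1
        # tie at -0.5 broken lexicographically
        assert r.ranks["B"] == 2 and r.ranks["C"] == 3

    def test_strict_winner_scores_one(self):
        recs = dwell_records("Ad1", {
            f"P{i:02d}": {"A": 900.0, "B": 100.0 + i, "C": 50.0 + i} for i in range(5)
        })
        r = dominance_scores(pairwise_dwell_matrix(recs))
        assert r.scores["A"] == pytest.approx(1.0)

    def test_strict_loser_scores_minus_one(self):
        recs = dwell_records("Ad1", {
            f"P{i:02d}": {"A": 10.0, "B": 100.0 + i, "C": 50.0 + i} for i in range(5)
        })
        r = dominance_scores(pairwise_dwell_matrix(recs))
        assert r.scores["A"] == pytest.approx(-1.0)

    def test_isolated_key_nan_with_warning(self):
        recs = dwell_records("Ad1", {
            "P01": {"A": 500.0, "B": 300.0, "C": None},
            "P02": {"A": 400.0, "B": 100.0, "C": None},
            "P03": {"A": None, "B": None, "C": 700.0},
        })
        r = dominance_scores(pairwise_dwell_matrix(recs))
        assert math.isnan(r.scores["C"])
        assert any("C" in w for w in r.warnings)
        assert "C" not in r.ordered_keys()


class TestCategoryLevel:
    def test_dwell_summed_within_category(self):
        # Text = 300 + 200 = 500 beats Image = 400
        recs = dwell_records("Ad1",
                             {"P01": {"t1": 300.0, "t2": 200.0, "img": 400.0}},
                             categories={"t1": "Text", "t2": "Text", "img": "Image"})
        m = category_dominance(recs)
        assert _cell(m, "Text", "Image/Visual") == 1.0

    def test_absent_categories_omitted(self):
        recs = dwell_records("Ad1", {"P01": {"a": 1.0, "b": 2.0}},
                             categories={"a": "Text", "b": "Image"})
        m = category_dominance(recs)
        assert set(m.keys) == {"Text", "Image/Visual"}


class TestPrecedence:
    def test_earlier_ttff_wins(self):
        recs = [
            make_record("P01", aoi="a", category="Text", ttff=200.0),
            make_record("P01", aoi="b", category="Image", ttff=800.0),
        ]
        m = ttff_precedence_matrix(recs)
        assert _cell(m, "Text", "Image/Visual") == 1.0

    def test_uncensored_beats_censored(self):
        recs = [
            make_record("P01", aoi="a", category="Text", ttff=9_000.0),
            make_record("P01", aoi="b", category="Image", censored=True),
        ]
        m = ttff_precedence_matrix(recs)
        assert _cell(m, "Text", "Image/Visual") == 1.0
        assert _support(m, "Text", "Image/Visual") == 1

    def test_both_censored_excluded(self):
        recs = [
            make_record("P01", aoi="a", category="Text", censored=True),
            make_record("P01", aoi="b", category="Image", censored=True),
            make_record("P02", aoi="a", category="Text", ttff=100.0),
            make_record("P02", aoi="b", category="Image", ttff=300.0),
        ]
        m = ttff_precedence_matrix(recs)
        assert _support(m, "Text", "Image/Visual") == 1

    def test_equal_latency_ties(self):
        recs = [
            make_record("P01", aoi="a", category="Text", ttff=400.0),
            make_record("P01", aoi="b", category="Image", ttff=400.0),
        ]
        m = ttff_precedence_matrix(recs)
        assert _cell(m, "Text", "Image/Visual") == 0.5

    def test_category_latency_is_min_over_aois(self):
        recs = [
            make_record("P01", aoi="t1", category="Text", ttff=900.0),
            make_record("P01", aoi="t2", category="Text", ttff=100.0),
            make_record("P01", aoi="img", category="Image", ttff=500.0),
        ]
        m = ttff_precedence_matrix(recs)
        assert _cell(m, "Text", "Image/Visual") == 1.0


class TestMaskAndAxioms:
    def _matrix(self):
        return pairwise_dwell_matrix(dwell_records("Ad1", {
            "P01": {"A": 3.0, "B": 2.0},
            "P02": {"A": 1.0, "B": 2.0},
        }))

    def test_mask_flags_low_support_only_for_display(self):
        m = self._matrix()
        masked = apply_support_mask(m, threshold=5)
        assert masked.mask[masked.keys.index("A"), masked.keys.index("B")]
        # P, N and scores unchanged
        assert np.array_equal(masked.N, m.N)
        np.testing.assert_array_equal(masked.P, m.P)
        assert dominance_scores(masked).scores == dominance_scores(m).scores

    def test_diagonal_never_masked(self):
        masked = apply_support_mask(self._matrix(), threshold=99)
        assert not masked.mask.diagonal().any()

    def test_axioms_pass_on_constructed_matrix(self):
        rep = verify_axioms(self._matrix())
        assert rep.passed
        assert rep.max_offdiag_deviation == 0.0
        assert rep.max_diag_deviation == 0.0

    def test_axioms_fail_on_corrupted_matrix(self):
        m = self._matrix()
        m.P[0, 1] += 0.01
        assert not verify_axioms(m).passed


class TestConcordance:
    def _table(self, dwells):
        return StudyTable(records=dwell_records("Ad1", dwells))

    def test_monotone_agreement_is_perfect(self):
        dwells = {f"P{i:02d}": {"A": 900.0 + i, "B": 500.0 + i, "C": 100.0 + i}
                  for i in range(4)}
        table = self._table(dwells)
        ranking = dominance_scores(pairwise_dwell_matrix(table.records))
        rep = concordance(ranking, benchmark_table(table))
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.pearson_r > 0.9

    def test_too_few_keys_rejected(self):
        table = self._table({"P01": {"A": 2.0, "B": 1.0}})
        ranking = dominance_scores(pairwise_dwell_matrix(table.records))
        with pytest.raises(ValidationError, match=">= 3"):
            concordance(ranking, benchmark_table(table))


# ---------------------------------------------------------------------------
# property tests with an independent brute-force oracle


def _oracle_pairwise(dwells):
    """Double-loop reference implementation over participant dicts."""
    keys = sorted({k for per in dwells.values() for k, v in per.items() if v is not None})
    P = {}
    for a in keys:
        for b in keys:
            if a == b:
                P[(a, b)] = 0.5
                continue
            wins = ties = n = 0
            for per in dwells.values():
                va, vb = per.get(a), per.get(b)
                if va is None or vb is None:
                    continue
                n += 1
                if va > vb:
                    wins += 1
                elif va == vb:
                    ties += 1
            P[(a, b)] = (wins + 0.5 * ties) / n if n else math.nan
    return keys, P


@st.composite
def _dwell_tables(draw):
    n_aois = draw(st.integers(2, 6))
    n_participants = draw(st.integers(1, 20))
    aois = [f"K{i}" for i in range(n_aois)]
    dwells = {}
    for p in range(n_participants):
        per = {}
        for a in aois:
            v = draw(st.one_of(st.none(),
                               st.sampled_from([100.0, 200.0, 300.0, 400.0])))
            per[a] = v
        dwells[f"P{p:02d}"] = per
    return dwells


@given(dwells=_dwell_tables())
@settings(derandomize=True, max_examples=100, deadline=None)
def test_matrix_matches_brute_force_oracle(dwells):
    keys, oracle = _oracle_pairwise(dwells)
    if len(keys) < 2:
        return
    m = pairwise_dwell_matrix(dwell_records("Ad1", dwells))
    assert m.keys == keys
    for i, a in enumerate(keys):
        for j, b in enumerate(keys):
            expect = oracle[(a, b)]
            got = m.P[i, j]
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect)


@given(dwells=_dwell_tables())
@settings(derandomize=True, max_examples=100, deadline=None)
def test_axioms_hold_on_random_tables(dwells):
    keys = {k for per in dwells.values() for k, v in per.items() if v is not None}
    if len(keys) < 2:
        return
    m = pairwise_dwell_matrix(dwell_records("Ad1", dwells))
    rep = verify_axioms(m, tol=1e-12)
    assert rep.passed


@given(dwells=_dwell_tables())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_scores_sum_to_zero_when_all_pairs_defined(dwells):
    keys = {k for per in dwells.values() for k, v in per.items() if v is not None}
    if len(keys) < 2:
        return
    m = pairwise_dwell_matrix(dwell_records("Ad1", dwells))
    if not m.defined().all():
        return
    total = sum(dominance_scores(m).scores.values())
    assert total == pytest.approx(0.0, abs=1e-12)


@given(dwells=_dwell_tables(), seed=st.integers(0, 2**16))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_permutation_equivariance(dwells, seed):
    keys = sorted({k for per in dwells.values() for k, v in per.items() if v is not None})
    if len(keys) < 2:
        return
    m1 = pairwise_dwell_matrix(dwell_records("Ad1", dwells))
    rng = np.random.default_rng(seed)
    rename = dict(zip(keys, rng.permutation([f"Z{i}" for i in range(len(keys))])))
    renamed = {p: {rename.get(a, a): v for a, v in per.items()} for p, per in dwells.items()}
    m2 = pairwise_dwell_matrix(dwell_records("Ad1", renamed))
    for i, a in enumerate(m1.keys):
        for j, b in enumerate(m1.keys):
            v1 = m1.P[i, j]
            v2 = m2.P[m2.keys.index(rename[a]), m2.keys.index(rename[b])]
            if math.isnan(v1):
                assert math.isnan(v2)
            else:
                # renaming can flip which member of the pair is computed
                # directly (the other is 1 - p), a one-ulp difference
                assert v1 == pytest.approx(v2, abs=1e-12)


@given(
    base=st.lists(st.floats(1, 1000), min_size=3, max_size=12),
    bump=st.floats(1.0, 500.0),
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_raising_one_key_never_lowers_its_score(base, bump):
    # two keys observed by everyone; increasing A's dwell everywhere can only
    # raise (or keep) its dominance score
    dwells = {f"P{i:02d}": {"A": v, "B": 400.0} for i, v in enumerate(base)}
    bumped = {p: {"A": per["A"] + bump, "B": per["B"]} for p, per in dwells.items()}
    s1 = dominance_scores(pairwise_dwell_matrix(dwell_records("Ad1", dwells))).scores["A"]
    s2 = dominance_scores(pairwise_dwell_matrix(dwell_records("Ad1", bumped))).scores["A"]
    assert s2 >= s1 - 1e-12
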