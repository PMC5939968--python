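import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conttest.benchmark_scoring import (
    conttest_score,
    format_ranked_table,
    precision_top_l5,
    score_case,
    summarize_methods,
    wilcoxon_signed_rank,
    CaseScore,
)
from conttest.contact_truth import ContactSet
from conttest.dca_predictor import PredictionList
from conttest.errors import DegenerateInputError, PairingError
from conttest.formats_io import Msa


def preds_of(pairs_scores):
    return PredictionList("p", tuple(pairs_scores))


def truth_of(L, pairs):
    return ContactSet(L=L, pairs=frozenset(pairs))


class TestPrecisionTopL5:
    def test_three_of_five(self):
        truth = truth_of(25, [(1, 25), (2, 26 - 1), (3, 27 - 1)][:1] + [(1, 25)])
        # construct explicitly: 5 long-range predictions, 3 true
        truth = truth_of(60, [(1, 30), (2, 31), (3, 32)])
        preds = preds_of(
            [(1, 30, 0.9), (2, 31, 0.8), (3, 32, 0.7), (4, 33, 0.6), (5, 34, 0.5)]
        )
        assert precision_top_l5(preds, truth, L=25) == pytest.approx(0.6)

    def test_all_true_gives_one(self):
        truth = truth_of(60, [(1, 30), (2, 31)])
        preds = preds_of([(1, 30, 0.9), (2, 31, 0.8)])
        assert precision_top_l5(preds, truth, L=10) == 1.0

    def test_k_is_floor_of_l_over_five(self):
        # L = 113 -> k = 22
        true_pairs = [(i, i + 30) for i in range(1, 23)]
        false_pairs = [(i, i + 40) for i in range(30, 60)]
        truth = truth_of(113, true_pairs)
        entries = [(i, j, 1000 - n) for n, (i, j) in enumerate(true_pairs)]
        entries += [(i, j, 10 - n * 0.1) for n, (i, j) in enumerate(false_pairs)]
        preds = preds_of(entries)
        assert precision_top_l5(preds, truth, L=113) == 1.0
        # sanity: 23rd true pair would not fit
        assert len([e for e in preds.entries[:22]]) == 22

    def test_short_range_predictions_filtered(self):
        truth = truth_of(60, [(1, 30), (2, 31)])
        preds = preds_of([(5, 6, 99.0), (1, 30, 0.5), (2, 31, 0.4)])
        assert precision_top_l5(preds, truth, L=10) == 1.0

    def test_missing_predictions_count_as_wrong(self):
        truth = truth_of(60, [(1, 30)])
        preds = preds_of([(1, 30, 0.5)])
        with pytest.warns(UserWarning, match="missing predictions"):
            assert precision_top_l5(preds, truth, L=60) == pytest.approx(1 / 12)

    def test_no_long_range_predictions_raises(self):
        truth = truth_of(60, [(1, 30)])
        preds = preds_of([(5, 6, 1.0)])
        with pytest.raises(DegenerateInputError):
            precision_top_l5(preds, truth, L=60)

    def test_adding_true_pair_never_decreases(self, rng):
        truth = truth_of(
            200, {(int(i), int(i) + 50) for i in rng.integers(1, 100, 30)}
        )
        entries = [(int(i), int(i) + 60, float(s)) for i, s in
                   zip(rng.integers(1, 100, 40), rng.random(40))]
        entries = list({(i, j): (i, j, s) for i, j, s in entries}.values())
        base = precision_top_l5(preds_of(entries), truth, L=100)
        extra = entries + [(1, 51, 2.0)]  # true pair with top score
        boosted = precision_top_l5(preds_of(extra), truth, L=100)
        assert boosted >= base


class TestConttestScore:
    def test_perfect(self):
        assert conttest_score([1.0, 1.0]) == 1.0

    def test_sqrt_identity(self):
        assert conttest_score([0.25, 1.0]) == pytest.approx(0.5)

    def test_zero_annihilates(self):
        assert conttest_score([0.0, 0.8]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            conttest_score([])

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=6))
    def test_geometric_at_most_arithmetic(self, values):
        assert conttest_score(values) <= np.mean(values) + 1e-12


def stub_predictor(precision_sequence, truth):
    """Predictor whose successive calls hit a prescribed precision."""
    calls = iter(precision_sequence)
    true_pairs = sorted(truth.pairs)

    def predict(msa, cmap):
        p = next(calls)
        k = 12  # L=60 -> k=12
        n_true = round(p * k)
        entries = [(i, j, 100.0 - n) for n, (i, j) in enumerate(true_pairs[:n_true])]
        falses = [(i, 40 + i, 50.0 - i) for i in range(1, 15)]
        falses = [(i, j, s) for i, j, s in falses if (i, j) not in truth.pairs]
        entries += falses[: k - n_true + 5]
        return PredictionList("stub", tuple(entries))

    return predict


@pytest.fixture
def toy_truth():
    return truth_of(60, [(i, i + 25) for i in range(1, 13)])


@pytest.fixture
def toy_msa():
    return Msa((("t", "A" * 60), ("u", "C" * 60)))


@pytest.fixture
def toy_cmap():
    from conttest.contact_truth import ColumnMap

    return ColumnMap(target_row_id="t", col_to_res={c: c for c in range(1, 61)})


class TestScoreCase:
    def test_single_replicate_two_predictors(self, toy_truth, toy_msa, toy_cmap):
        predictors = {
            "a": stub_predictor([0.5], toy_truth),
            "b": stub_predictor([0.5], toy_truth),
        }
        cs = score_case([toy_msa], toy_truth, [toy_cmap], predictors)
        assert cs.conttest_score == pytest.approx(0.5)

    def test_replicates_averaged_before_geometric_mean(
        self, toy_truth, toy_msa, toy_cmap
    ):
        predictors = {
            "a": stub_predictor([0.25, 0.5], toy_truth),
            "b": stub_predictor([0.25, 0.25], toy_truth),
        }
        cs = score_case([toy_msa, toy_msa], toy_truth, [toy_cmap] * 2, predictors)
        # means: a = 0.375, b = 0.25; geometric mean = sqrt(0.09375)
        assert cs.per_predictor["a"][1] == pytest.approx(0.375)
        assert cs.conttest_score == pytest.approx(np.sqrt(0.375 * 0.25))

    def test_zero_predictor_zeroes_case(self, toy_truth, toy_msa, toy_cmap):
        predictors = {
            "a": stub_predictor([1.0], toy_truth),
            "b": stub_predictor([0.0], toy_truth),
        }
        cs = score_case([toy_msa], toy_truth, [toy_cmap], predictors)
        assert cs.conttest_score == 0.0

    def test_invariant_to_predictor_order(self, toy_truth, toy_msa, toy_cmap):
        p1 = {
            "a": stub_predictor([0.5], toy_truth),
            "b": stub_predictor([0.25], toy_truth),
        }
        p2 = {
            "b": stub_predictor([0.25], toy_truth),
            "a": stub_predictor([0.5], toy_truth),
        }
        s1 = score_case([toy_msa], toy_truth, [toy_cmap], p1).conttest_score
        s2 = score_case([toy_msa], toy_truth, [toy_cmap], p2).conttest_score
        assert s1 == pytest.approx(s2)


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-sided p by brute-force enumeration of all 2^n sign
    assignments of the ranked absolute differences."""
    from scipy.stats import rankdata

    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    n = len(diffs)
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    p_low = np.mean(w_all <= w_obs + 1e-9)
    p_high = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_five_positive_distinct(self):
        pairs = [(k + 1.0, 0.0) for k in range(5)]
        stat, p = wilcoxon_signed_rank(pairs)
        assert stat == 15.0
        assert p == pytest.approx(0.0625)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([(1.0, 1.0)] * 4)
        assert p == 1.0

    def test_antisymmetry(self, rng):
        diffs = rng.normal(size=12)
        p_pos = wilcoxon_signed_rank([(d, 0.0) for d in diffs])[1]
        p_neg = wilcoxon_signed_rank([(0.0, d) for d in diffs])[1]
        assert p_pos == pytest.approx(p_neg)

    def test_exact_matches_enumeration_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 11))
            diffs = np.round(rng.normal(size=n), 2)
            # occasional exact ties in |d|
            if n > 4:
                diffs[1] = -diffs[0]
            pairs = [(d, 0.0) for d in diffs if d != 0]
            if not pairs:
                continue
            _, p = wilcoxon_signed_rank(pairs)
            assert p == pytest.approx(wilcoxon_enumeration_oracle([d for d, _ in pairs]))

    def test_large_n_uses_normal_approximation(self, rng):
        diffs = rng.normal(0.5, 1.0, size=60)
        _, p = wilcoxon_signed_rank([(d, 0.0) for d in diffs])
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(diffs, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)


def case_scores(name_to_values):
    return {
        method: [
            CaseScore(case_id=f"c{k}", per_predictor={}, conttest_score=v)
            for k, v in enumerate(values)
        ]
        for method, values in name_to_values.items()
    }


class TestSummarizeMethods:
    def test_identical_methods_not_significant(self):
        per_method = case_scores({"a": [0.5] * 10, "b": [0.5] * 10})
        rows = summarize_methods(per_method)
        assert rows[0]["p_vs_next"] == 1.0
        assert rows[0]["mark"] == "NS"

    def test_uniform_improvement_is_significant(self, rng):
        base = rng.uniform(0.2, 0.7, size=20)
        per_method = case_scores({"worse": base, "better": base + 0.1})
        rows = summarize_methods(per_method)
        assert rows[0]["method"] == "better"
        assert rows[0]["p_vs_next"] < 0.001
        assert rows[0]["mark"] == "***"

    def test_single_method_table(self):
        rows = summarize_methods(case_scores({"only": [0.4, 0.6]}))
        assert len(rows) == 1
        assert rows[0]["p_vs_next"] is None

    def test_mismatched_case_sets_rejected(self):
        per_method = case_scores({"a": [0.5] * 3, "b": [0.5] * 4})
        with pytest.raises(PairingError):
            summarize_methods(per_method)

    def test_table_formatting_smoke(self):
        rows = summarize_methods(case_scores({"a": [0.5] * 5, "b": [0.6] * 5}))
        text = format_ranked_table(rows)
        assert "a" in text and "b" in text
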