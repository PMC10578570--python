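import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcqkit import (
    ResponseMatrix,
    ScoringError,
    consistency_profile,
    estimate_k_from_profile,
    proportion_delayed,
    score_cohort,
    score_respondent,
)
from mcqkit.item_bank import SET_LABELS

from conftest import make_matrix

LADDER9 = [0.00016, 0.0004, 0.001, 0.0025, 0.006, 0.016, 0.041, 0.1, 0.25]


# ----------------------------------------------------------------------
# independent brute-force oracle: enumerate all switch positions and count
# consistent responses directly, one loop at a time
# ----------------------------------------------------------------------

def oracle_profile(pattern):
    n = len(pattern)
    return [
        (
            sum(1 for v in pattern[:s] if v == 0)
            + sum(1 for v in pattern[s:] if v == 1)
        )
        / n
        for s in range(n + 1)
    ]


def oracle_estimate(pattern, ks):
    prof = oracle_profile(pattern)
    best = max(prof)
    logs = []
    for s, p in enumerate(prof):
        if abs(p - best) < 1e-12:
            if s == 0:
                logs.append(math.log(ks[0]))
            elif s == len(ks):
                logs.append(math.log(ks[-1]))
            else:
                logs.append((math.log(ks[s - 1]) + math.log(ks[s])) / 2)
    return math.exp(sum(logs) / len(logs)), best


class TestConsistencyProfile:
    def test_all_delayed_max_at_zero(self):
        prof = consistency_profile([1] * 9)
        assert prof[0] == 1.0
        assert prof.argmax() == 0

    def test_all_immediate_max_at_end(self):
        prof = consistency_profile([0] * 9)
        assert prof[9] == 1.0
        assert prof.argmax() == 9

    def test_clean_switch_pattern(self):
        prof = consistency_profile([0, 0, 0, 1, 1, 1, 1, 1, 1])
        assert prof[3] == 1.0
        assert (prof < 1.0).sum() == 9  # unique maximum
        assert prof[2] == pytest.approx(8 / 9)

    def test_entries_are_multiples_of_one_over_n(self):
        prof = consistency_profile([1, 0, 1, 0, 1])
        assert np.allclose(np.round(prof * 5), prof * 5)

    def test_missing_raises(self):
        with pytest.raises(ScoringError, match="impute"):
            consistency_profile([1, float("nan"), 0])

    def test_empty_raises(self):
        with pytest.raises(ScoringError):
            consistency_profile([])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=27))
    def test_matches_oracle(self, pattern):
        assert np.allclose(consistency_profile(pattern), oracle_profile(pattern))


class TestEstimateFromProfile:
    def test_clean_switch_geometric_mean(self):
        ks = [0.0025, 0.01, 0.04, 0.16]
        pattern = [0, 1, 1, 1]  # switch between items 1 and 2
        k, c = estimate_k_from_profile(consistency_profile(pattern), ks)
        assert k == pytest.approx(math.sqrt(0.01 * 0.0025))
        pattern = [0, 0, 1, 1]
        k, c = estimate_k_from_profile(consistency_profile(pattern), ks)
        assert k == pytest.approx(math.sqrt(0.01 * 0.04))
        assert c == 1.0

    def test_all_delayed_boundary(self):
        ks = LADDER9
        k, c = estimate_k_from_profile(consistency_profile([1] * 9), ks)
        assert k == pytest.approx(min(ks))
        assert c == 1.0

    def test_all_immediate_boundary(self):
        ks = LADDER9
        k, c = estimate_k_from_profile(consistency_profile([0] * 9), ks)
        assert k == pytest.approx(max(ks))

    def test_tie_rule_geometric_mean_of_candidates(self, bank21):
        # adjacent positions can never tie (consecutive counts differ by
        # exactly 1), so the smallest genuine tie is two positions apart:
        # pattern 1,0,1,1,1,1,1 ties positions 0 and 2, whose candidates are
        # k1 and sqrt(k2 k3); the estimate is their geometric mean.
        ks = [it.k_nominal for it in bank21.set_items("small")]
        pattern = [1, 0, 1, 1, 1, 1, 1]
        k, c = estimate_k_from_profile(consistency_profile(pattern), ks)
        expect = (ks[0] ** 2 * ks[1] * ks[2]) ** 0.25
        assert k == pytest.approx(expect)
        assert c == pytest.approx(6 / 7)
        ek, ec = oracle_estimate(pattern, ks)
        assert k == pytest.approx(ek) and c == pytest.approx(ec)

    def test_empty_items_raise(self):
        with pytest.raises(ScoringError):
            estimate_k_from_profile([1.0], [])

    @settings(max_examples=200)
    @given(
        pattern=st.lists(st.integers(0, 1), min_size=2, max_size=9),
    )
    def test_oracle_equivalence_and_bounded_range(self, pattern):
        ks = LADDER9[: len(pattern)]
        expect_k, expect_c = oracle_estimate(pattern, ks)
        k, c = estimate_k_from_profile(consistency_profile(pattern), ks)
        assert k == pytest.approx(expect_k)
        assert c == pytest.approx(expect_c)
        assert min(ks) * (1 - 1e-12) <= k <= max(ks) * (1 + 1e-12)

    def test_profile_depends_only_on_pattern_and_order(self):
        # same pattern, two k ladders: identical profile, estimate moves
        pattern = [0, 0, 1, 1, 1]
        p = consistency_profile(pattern)
        k_a, _ = estimate_k_from_profile(p, [0.001, 0.002, 0.004, 0.008, 0.016])
        k_b, _ = estimate_k_from_profile(p, [0.1, 0.2, 0.4, 0.8, 1.6])
        assert k_a != k_b  # amounts/k values only enter through the ladder


class TestProportionDelayed:
    def test_all_delayed(self):
        assert proportion_delayed([1] * 27) == 1.0

    def test_alternating(self):
        assert proportion_delayed([0, 1] * 10) == 0.5

    def test_third(self):
        assert proportion_delayed([1] * 9 + [0] * 18) == pytest.approx(1 / 3)

    def test_ignores_missing(self):
        assert proportion_delayed([1, float("nan"), 0, 1]) == pytest.approx(2 / 3)

    def test_all_missing_raises(self):
        with pytest.raises(ScoringError):
            proportion_delayed([float("nan")] * 3)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=27))
    def test_flip_to_immediate_never_increases(self, pattern):
        base = proportion_delayed(pattern)
        for i, v in enumerate(pattern):
            if v == 1:
                flipped = list(pattern)
                flipped[i] = 0
                assert proportion_delayed(flipped) <= base


class TestScoreRespondent:
    def test_all_delayed_27(self, bank27):
        res = score_respondent(bank27, [1] * 27)
        k_min = min(it.k_nominal for it in bank27)
        for field in ("overall_k", "small_k", "medium_k", "large_k", "composite_k"):
            assert getattr(res, field) == pytest.approx(k_min)
        assert res.proportion_delayed == 1.0
        assert res.consistency_overall == 1.0

    def test_missing_in_small_set(self, bank27):
        pattern = [1.0] * 27
        small_col = bank27.set_items("small")[0].item_id - 1
        pattern[small_col] = float("nan")
        res = score_respondent(bank27, pattern)
        assert res.small_k is None
        assert res.overall_k is None
        assert res.composite_k is None  # strict rule
        assert res.medium_k is not None and res.large_k is not None
        assert res.n_missing == 1

    def test_composite_is_geometric_mean_of_sets(self, bank27):
        # craft per-set switch points at ranks 2, 4 and 6
        pattern = [0.0] * 27
        targets = {"small": 2, "medium": 4, "large": 6}
        for label, switch in targets.items():
            for it in bank27.set_items(label):
                pattern[it.item_id - 1] = 1.0 if it.k_rank > switch else 0.0
        res = score_respondent(bank27, pattern)
        expected = {}
        for label, switch in targets.items():
            ladder = [it.k_nominal for it in bank27.set_items(label)]
            expected[label] = math.sqrt(ladder[switch - 1] * ladder[switch])
        assert res.small_k == pytest.approx(expected["small"])
        assert res.medium_k == pytest.approx(expected["medium"])
        assert res.large_k == pytest.approx(expected["large"])
        geo = math.exp(sum(math.log(v) for v in expected.values()) / 3)
        assert res.composite_k == pytest.approx(geo)

    def test_composite_of_equal_set_ks_is_that_k(self, bank27):
        # all three sets switch at the same rank -> composite equals set k
        pattern = [0.0] * 27
        for it in bank27:
            pattern[it.item_id - 1] = 1.0 if it.k_rank > 5 else 0.0
        res = score_respondent(bank27, pattern)
        assert res.composite_k == pytest.approx(res.small_k)

    def test_length_mismatch(self, bank27):
        with pytest.raises(ScoringError):
            score_respondent(bank27, [1] * 21)


class TestScoreCohort:
    def test_identical_rows_identical_results(self, bank21):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 2, 21).astype(float)
        mat = make_matrix([row, row])
        df = score_cohort(bank21, mat)
        a, b = df.drop(columns="respondent_id").iloc[0], df.drop(
            columns="respondent_id"
        ).iloc[1]
        assert a.equals(b)

    def test_empty_matrix(self, bank21):
        mat = ResponseMatrix(ids=(), values=np.empty((0, 21)))
        df = score_cohort(bank21, mat)
        assert len(df) == 0

    def test_count_preserved_on_synthetic_cohort(self, bank21):
        from mcqkit import default_config, generate_cohort

        mat, _ = generate_cohort(bank21, default_config(bank21, seed=2))
        df = score_cohort(bank21, mat)
        assert len(df) == 900
        assert list(df["respondent_id"]) == list(mat.ids)
        assert df["composite_k"].notna().all()

    def test_matches_single_respondent_path(self, bank27):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 2, (8, 27)).astype(float)
        mat = make_matrix(vals)
        df = score_cohort(bank27, mat)
        for i in range(8):
            res = score_respondent(bank27, vals[i])
            assert df["overall_k"].iloc[i] == pytest.approx(res.overall_k)
            assert df["composite_k"].iloc[i] == pytest.approx(res.composite_k)

    def test_estimates_within_instrument_range(self, bank):
        rng = np.random.default_rng(11)
        n = bank.version
        vals = rng.integers(0, 2, (200, n)).astype(float)
        df = score_cohort(bank, make_matrix(vals))
        k_min = min(it.k_nominal for it in bank)
        k_max = max(it.k_nominal for it in bank)
        for col in ("overall_k", "small_k", "medium_k", "large_k", "composite_k"):
            assert df[col].between(k_min * (1 - 1e-12), k_max * (1 + 1e-12)).all()


class TestMonotoneRecovery:
    """Noise-free respondents are scored to the geometric mean of their
    bracketing rank interval with perfect consistency."""

    @pytest.mark.parametrize("version", [21, 27])
    def test_every_interior_interval(self, version, bank21, bank27):
        import pandas as pd

        from mcqkit import simulate_responses

        bank = bank21 if version == 21 else bank27
        ladder = np.log(bank.k_ladder("small"))
        mids = (ladder[:-1] + ladder[1:]) / 2
        respondents = pd.DataFrame(
            {
                "respondent_id": [str(i) for i in range(len(mids))],
                "true_ln_k": mids,
                "covariate": 0.0,
            }
        )
        mat = simulate_responses(
            bank, respondents, float("inf"), np.random.default_rng(0)
        )
        df = score_cohort(bank, mat)
        for i in range(len(mids)):
            expect = math.exp(mids[i])  # midpoint == geomean of bracketing ks
            for col in ("small_k", "medium_k", "large_k", "composite_k", "overall_k"):
                assert df[col].iloc[i] == pytest.approx(expect), (i, col)
        assert (df.filter(like="consistency") == 1.0).all().all()
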