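"""Questionnaire scales and statistics, checked against brute-force oracles."""

from itertools import combinations, permutations, product as iproduct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from neuroorganoleptics.sensory_stats import (
    attach_feature_diffs,
    hedonic_summary,
    kendall_repeatability,
    nps_categorize,
    preference_rank_sums,
    select_opposed_pairs,
    sign_fraction,
    wilcoxon_matrix,
)
from neuroorganoleptics.synthetic_session import draw_window_powers


# ---------------------------------------------------------------- oracles

def signed_rank_exact_p(diffs):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in iproduct([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p = 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs))
    return min(p, 1.0)


def kendall_exact(a, b):
    """Tau and permutation p by brute force over all orderings of b."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)

    def tau(x, y):
        s = 0
        for i, j in combinations(range(n), 2):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        return s / (n * (n - 1) / 2)

    t_obs = tau(a, b)
    taus = [tau(a, np.asarray(perm)) for perm in permutations(b)]
    p = np.mean([abs(t) >= abs(t_obs) - 1e-12 for t in taus])
    return t_obs, float(p)


def friedman_statistic_formula(ranks):
    """Direct formula: 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)."""
    R = np.asarray(ranks, dtype=float)
    n, k = R.shape
    sums = R.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(sums**2) - 3.0 * n * (k + 1)


# ------------------------------------------------------------------ tests

class TestNPS:
    @pytest.mark.parametrize("score,category", [
        (9, "promoter"), (10, "promoter"),
        (7, "passively_satisfied"), (8, "passively_satisfied"),
        (0, "detractor"), (6, "detractor"),
    ])
    def test_category_edges(self, score, category):
        assert nps_categorize(score) == category

    def test_partition_covers_scale_without_gaps(self):
        cats = [nps_categorize(s) for s in range(11)]
        assert cats == ["detractor"] * 7 + ["passively_satisfied"] * 2 + ["promoter"] * 2

    @pytest.mark.parametrize("score", [-1, 11, 5.5])
    def test_out_of_scale_rejected(self, score):
        with pytest.raises(ValueError):
            nps_categorize(score)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject", "session", "product", "question", "response"]
    )


class TestOpposedPairs:
    def _scores(self, a, b):
        return _table([
            ("s1", 1, "A", "global_acceptance", a),
            ("s1", 1, "B", "global_acceptance", b),
        ])

    @pytest.mark.parametrize("a,b,selected", [(9, 4, True), (6, 1, True), (8, 5, False)])
    def test_five_point_criterion_boundary(self, a, b, selected):
        pairs = select_opposed_pairs(self._scores(a, b))
        assert (len(pairs) == 1) is selected

    def test_pairs_oriented_high_low(self):
        pairs = select_opposed_pairs(self._scores(3, 9))
        r = pairs.iloc[0]
        assert r["product_high"] == "B" and r["product_low"] == "A"
        assert r["score_high"] - r["score_low"] >= 5

    def test_cross_subject_scores_never_paired(self):
        t = _table([
            ("s1", 1, "A", "global_acceptance", 9),
            ("s2", 1, "B", "global_acceptance", 1),
        ])
        assert len(select_opposed_pairs(t)) == 0


class TestSignFraction:
    def test_direct_count(self):
        pairs = pd.DataFrame({"lf_power_diff": [1.0, 2.0, -1.0, 3.0]})
        assert sign_fraction(pairs, "lf_power") == 0.75

    def test_all_negative_is_zero(self):
        pairs = pd.DataFrame({"lf_power_diff": [-1.0, -0.5]})
        assert sign_fraction(pairs, "lf_power") == 0.0

    def test_ties_count_as_non_positive(self):
        pairs = pd.DataFrame({"lf_power_diff": [0.0, 1.0]})
        assert sign_fraction(pairs, "lf_power") == 0.5

    def test_empty_pairs_undefined(self):
        with pytest.raises(ValueError):
            sign_fraction(pd.DataFrame({"lf_power_diff": []}), "lf_power")

    @given(
        diffs=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30),
        seed=st.integers(0, 1000),
    )
    @settings(deadline=None, max_examples=40)
    def test_invariant_to_order_and_monotone_transform(self, diffs, seed):
        rng = np.random.default_rng(seed)
        pairs = pd.DataFrame({"f_diff": diffs})
        base = sign_fraction(pairs, "f")
        shuffled = pairs.sample(frac=1.0, random_state=seed)
        assert sign_fraction(shuffled, "f") == base
        # strictly monotone odd transform preserves every sign
        transformed = pd.DataFrame({"f_diff": np.cbrt(diffs)})
        assert sign_fraction(transformed, "f") == base

    def test_direction_recovered_under_negative_coupling(self):
        # Low acceptance -> higher LF: the low-minus-high LF difference of
        # opposed pairs should be positive more often than not.
        for seed in range(5):
            rng = np.random.default_rng(seed)
            diffs = []
            for _ in range(100):
                lf_low, _ = draw_window_powers(2, 600, 400, coupling=0.5, rng=rng)
                lf_high, _ = draw_window_powers(8, 600, 400, coupling=0.5, rng=rng)
                diffs.append(lf_low - lf_high)
            frac = sign_fraction(pd.DataFrame({"lf_power_diff": diffs}), "lf_power")
            assert frac > 0.5


class TestWilcoxonMatrix:
    def _features(self, values_by_product, n=None):
        rows = []
        for product, vals in values_by_product.items():
            for i, v in enumerate(vals):
                rows.append({"subject": f"s{i}", "session": 1, "product": product, "value": v})
        return pd.DataFrame(rows)

    def test_identical_paired_samples_not_significant(self):
        vals = list(np.linspace(1, 2, 8))
        p, mask = wilcoxon_matrix(self._features({"A": vals, "B": vals}), "value")
        assert p.loc["A", "B"] == 1.0
        assert not mask.loc["A", "B"]

    def test_six_uniform_positive_diffs_exact_p(self):
        # All six differences share one sign: the most extreme signed-rank
        # outcome, two-sided p = 2/2^6.
        a = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        b = [4.0, 4.5, 5.0, 6.0, 7.0, 8.0]
        p, _ = wilcoxon_matrix(self._features({"A": a, "B": b}), "value")
        assert p.loc["A", "B"] == pytest.approx(2 / 64)
        assert p.loc["A", "B"] == pytest.approx(signed_rank_exact_p(np.array(a) - np.array(b)))

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        feats = self._features({p: rng.normal(size=10) for p in "ABC"})
        p, _ = wilcoxon_matrix(feats, "value")
        assert np.allclose(p.to_numpy(), p.to_numpy().T, equal_nan=True)

    def test_exactness_against_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for n in (5, 6, 8):
            a = rng.normal(2, 1, n)
            b = rng.normal(1.2, 1, n)
            p, _ = wilcoxon_matrix(self._features({"A": a, "B": b}), "value")
            assert p.loc["A", "B"] == pytest.approx(signed_rank_exact_p(a - b))

    def test_insufficient_observations_undefined(self):
        p, _ = wilcoxon_matrix(self._features({"A": [1, 2], "B": [2, 3]}), "value")
        assert np.isnan(p.loc["A", "B"])


class TestKendallRepeatability:
    def test_perfect_concordance(self):
        tau, p, verdict = kendall_repeatability([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert tau == pytest.approx(1.0)
        assert verdict == "correlated"

    def test_perfect_reversal(self):
        tau, _, _ = kendall_repeatability([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_hand_sample_matches_brute_force_enumeration(self):
        a = [3, 1, 4, 2, 5]
        b = [2, 1, 5, 3, 4]
        tau, p, _ = kendall_repeatability(a, b)
        tau_o, p_o = kendall_exact(a, b)
        assert tau == pytest.approx(tau_o)
        assert p == pytest.approx(p_o)

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError):
            kendall_repeatability([5, 5, 5, 5], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            kendall_repeatability([1, 2, 3], [1, 2, 3])


class TestPreferenceRankSums:
    def test_unanimous_ordering_forces_rank_sums(self):
        R = pd.DataFrame([[1, 2, 3, 4]] * 10, columns=list("abcd"))
        res = preference_rank_sums(R)
        assert res.rank_sums.tolist() == [10, 20, 30, 40]
        assert res.n_subjects == 10

    def test_even_split_two_items_not_significant(self):
        R = pd.DataFrame([[1, 2]] * 5 + [[2, 1]] * 5, columns=["x", "y"])
        res = preference_rank_sums(R)
        assert res.rank_sums["x"] == res.rank_sums["y"]
        assert not res.significant_pairs["significant"].any()

    def test_friedman_statistic_matches_direct_formula(self):
        R = pd.DataFrame(
            [[1, 2, 3], [2, 1, 3], [1, 3, 2], [1, 2, 3]], columns=list("xyz")
        )
        res = preference_rank_sums(R)
        assert res.friedman_statistic == pytest.approx(friedman_statistic_formula(R))

    def test_incomplete_rows_dropped_with_count(self):
        R = pd.DataFrame([[1, 2, 3], [1, 1, 3], [3, 2, 1]], columns=list("xyz"))
        res = preference_rank_sums(R)
        assert res.n_dropped == 1
        assert res.n_subjects == 2


class TestHedonicSummary:
    def _uniform_table(self):
        rows = [("s%d" % i, 1, "A", "global_acceptance", 1 + i % 9) for i in range(18)]
        return _table(rows)

    def test_point_mass(self):
        t = _table([("s1", 1, "A", "global_acceptance", 9)] * 3
                   + [("s1", 2, "A", "global_acceptance", 9)])
        hist, desc = hedonic_summary(t, "A")
        assert hist.loc[9, 1] == 3 and hist.loc[9, 2] == 1
        assert desc["mean"].tolist() == [9.0, 9.0]
        assert desc["sd"].tolist() == [0.0, 0.0]

    def test_uniform_scores_mean_five(self):
        hist, desc = hedonic_summary(self._uniform_table(), "A")
        assert desc["mean"].iloc[0] == pytest.approx(5.0)

    def test_histogram_mass_conserved(self):
        hist, desc = hedonic_summary(self._uniform_table(), "A")
        assert hist.to_numpy().sum() == desc["n"].sum() == 18


class TestAttachFeatureDiffs:
    def test_low_minus_high_orientation(self):
        pairs = pd.DataFrame([{
            "subject": "s1", "session": 1, "product_high": "A", "product_low": "B",
            "score_high": 9, "score_low": 3,
        }])
        feats = pd.DataFrame([
            {"subject": "s1", "session": 1, "product": "A",
             "lf_power": 10.0, "hf_power": 5.0, "lf_norm": 0.6, "hf_norm": 0.4},
            {"subject": "s1", "session": 1, "product": "B",
             "lf_power": 14.0, "hf_power": 4.0, "lf_norm": 0.7, "hf_norm": 0.3},
        ])
        out = attach_feature_diffs(pairs, feats)
        assert out["lf_power_diff"].iloc[0] == pytest.approx(4.0)
        assert out["hf_power_diff"].iloc[0] == pytest.approx(-1.0)

    def test_pairs_missing_windows_dropped(self):
        pairs = pd.DataFrame([{
            "subject": "s1", "session": 1, "product_high": "A", "product_low": "B",
            "score_high": 9, "score_low": 3,
        }])
        feats = pd.DataFrame([
            {"subject": "s1", "session": 1, "product": "A",
             "lf_power": 1.0, "hf_power": 1.0, "lf_norm": 0.5, "hf_norm": 0.5},
        ])
        assert len(attach_feature_diffs(pairs, feats)) == 0
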