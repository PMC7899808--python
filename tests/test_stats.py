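import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from breezesim import (
    cohen_kappa,
    friedman_test,
    run_analysis,
    summarize_conditions,
    wilcoxon_signed_rank,
)


def brute_force_exact_p(d):
    """Two-sided signed-rank p by literally enumerating all 2^n sign vectors."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sp_stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.array(w_all)
    p_le = np.mean(w_all <= w_obs)
    p_ge = np.mean(w_all >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSummarize:
    def test_constant_sample(self):
        s = summarize_conditions(np.full(10, 3.0))
        assert s.sd == 0.0
        assert s.iqr_low == s.median == s.iqr_high == 3.0

    def test_linear_interpolation_quartiles(self):
        s = summarize_conditions(np.arange(1.0, 17.0))
        assert s.median == pytest.approx(8.5)
        assert s.iqr_low == pytest.approx(4.75)
        assert s.iqr_high == pytest.approx(12.25)

    def test_single_observation_has_undefined_sd(self):
        assert math.isnan(summarize_conditions(np.array([5.0])).sd)


class TestFriedman:
    def test_no_differences_gives_zero_statistic(self):
        data = np.tile([3.0, 3.0, 3.0], (8, 1))
        res = friedman_test(data)
        assert res.q == 0.0
        assert res.p == 1.0

    def test_unanimous_ordering_sixteen_subjects(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(16, 1))
        data = base + np.array([0.0, 1.0, 2.0]) + 0.01 * rng.random((16, 3))
        # every subject ranks the columns 1 < 2 < 3
        res = friedman_test(np.sort(data, axis=1))
        assert res.q == pytest.approx(32.0)
        assert res.df == 2
        assert res.p < 0.001

    def test_three_conditions_have_two_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        res = friedman_test(rng.normal(size=(16, 3)))
        assert res.df == 2

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(12, 3))
        a = friedman_test(data)
        b = friedman_test(np.exp(data))  # strictly increasing
        assert b.q == pytest.approx(a.q)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(10, 4))
        ours = friedman_test(data)
        theirs = sp_stats.friedmanchisquare(*data.T)
        assert ours.q == pytest.approx(theirs.statistic)
        assert ours.p == pytest.approx(theirs.pvalue)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, 2.0, 3.0]]))


class TestWilcoxon:
    def test_all_positive_differences(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=16)
        x = y + rng.uniform(0.5, 2.0, size=16)
        res = wilcoxon_signed_rank(x, y)
        assert res.w == 0.0
        assert res.rbc == 1.0
        assert res.method == "exact"
        assert res.p < 0.001

    def test_three_pair_example_against_enumeration(self):
        x = np.array([1.0, 0.0, 3.0])
        y = np.array([0.0, 2.0, 0.0])  # d = [1, -2, 3]
        res = wilcoxon_signed_rank(x, y)
        assert res.w == 2.0
        assert res.rbc == pytest.approx(1 / 3)
        assert res.p == pytest.approx(brute_force_exact_p([1, -2, 3]))
        assert res.p == pytest.approx(0.75)

    def test_negative_rank_sum_nineteen_reproduces_rbc_0721(self):
        # n = 16 tie-free differences, negatives at ranks 3 and 16
        d = np.arange(1.0, 17.0)
        d[2] *= -1
        d[15] *= -1
        res = wilcoxon_signed_rank(d, np.zeros(16))
        assert min(res.w, 136 - res.w) == 19.0
        assert round(res.rbc, 3) == 0.721

    def test_zero_differences_are_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 1.0, 2.0, 3.0, 3.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.n_effective == 4

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_ties_switch_to_normal_approximation(self):
        x = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        y = np.zeros(6)
        y[0] = 4.0
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal_approx"
        ref = sp_stats.wilcoxon(x, y, correction=False, mode="approx")
        assert res.p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            d = rng.normal(size=n) * 10
            d = d[d != 0]
            if len(np.unique(np.abs(d))) < len(d):
                continue
            res = wilcoxon_signed_rank(d, np.zeros_like(d))
            assert res.p == pytest.approx(brute_force_exact_p(d), abs=1e-12)

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(17)
        d = rng.normal(size=14)
        res = wilcoxon_signed_rank(d, np.zeros(14))
        ref = sp_stats.wilcoxon(d, mode="exact")
        assert res.p == pytest.approx(ref.pvalue)
        assert res.w == pytest.approx(ref.statistic)

    def test_rank_biserial_identity_single_signed_sample(self):
        # with all nonzero d of one sign, rbc = 1 - 2 w / S
        d = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        res = wilcoxon_signed_rank(d, np.zeros(5))
        s = 5 * 6 / 2
        assert res.rbc == pytest.approx(1 - 2 * res.w / s)

    def test_table_row_consistency_reconstruction(self):
        # |rbc| = (S - 2 w) / S for any tie-free row
        rng = np.random.default_rng(23)
        for _ in range(20):
            d = rng.normal(size=16)
            res = wilcoxon_signed_rank(d, np.zeros(16))
            s = res.n_effective * (res.n_effective + 1) / 2
            assert abs(res.rbc) == pytest.approx((s - 2 * res.w) / s)
            assert -1.0 <= res.rbc <= 1.0


class TestCohenKappa:
    def test_identical_sequences(self):
        res = cohen_kappa(list("abcabc"), list("abcabc"))
        assert res.p_o == 1.0
        assert res.kappa == 1.0

    def test_two_by_two_confusion_example(self):
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        res = cohen_kappa(a, b)
        assert res.p_o == pytest.approx(0.7)
        assert res.kappa == pytest.approx(0.4)

    def test_shuffled_coder_has_no_agreement_beyond_chance(self):
        rng = np.random.default_rng(6)
        labels = list(rng.choice(["p", "q", "r"], size=60))
        kappas = []
        for _ in range(300):
            shuffled = list(rng.permutation(labels))
            kappas.append(cohen_kappa(labels, shuffled).kappa)
        assert abs(np.mean(kappas)) < 0.02

    def test_kappa_never_exceeds_raw_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.choice(["u", "v"], size=30)
            b = rng.choice(["u", "v"], size=30)
            if np.all(a == b):
                continue
            res = cohen_kappa(list(a), list(b))
            assert res.kappa <= res.p_o + 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(8)
        a = list(rng.choice(["u", "v", "w"], size=40))
        b = list(rng.choice(["u", "v", "w"], size=40))
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a", "b"])


def tidy(measure_values):
    """Build a tidy frame from {measure: (n x 3 array)}."""
    rows = []
    for measure, arr in measure_values.items():
        for i, row in enumerate(arr):
            for cond, v in zip(("BASELINE", "CIRCLE", "BREEZE"), row):
                rows.append(
                    {"measure": measure, "subject": f"S{i:02d}",
                     "condition": cond, "value": v}
                )
    return pd.DataFrame(rows)


class TestRunAnalysis:
    def test_nonsignificant_measures_are_excluded_from_pairwise(self):
        rng = np.random.default_rng(9)
        null = rng.normal(size=(16, 3))
        effect = rng.normal(size=(16, 3)) + np.array([0.0, 5.0, 5.0])
        report = run_analysis(tidy({"flat": null, "shifted": effect}))
        assert set(report.pairwise.measure) == {"shifted"}
        omni = report.omnibus.set_index("measure")
        assert not omni.loc["flat", "significant"]
        assert omni.loc["shifted", "significant"]

    def test_pairwise_rows_follow_the_reporting_order(self):
        rng = np.random.default_rng(10)
        effect = rng.normal(size=(16, 3)) + np.array([0.0, 5.0, 5.0])
        report = run_analysis(tidy({"m": effect}))
        pairs = list(zip(report.pairwise.condition, report.pairwise.reference))
        assert pairs == [("CIRCLE", "BASELINE"), ("BREEZE", "BASELINE"),
                         ("BREEZE", "CIRCLE")]

    def test_missing_condition_rejected(self):
        df = tidy({"m": np.random.default_rng(11).normal(size=(8, 3))})
        df = df[df.condition != "BREEZE"]
        with pytest.raises(ValueError, match="incomplete"):
            run_analysis(df)

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(12)
        effect = rng.normal(size=(16, 3)) + np.array([0.0, 5.0, 5.5])
        plain = run_analysis(tidy({"m": effect}), holm=False)
        adj = run_analysis(tidy({"m": effect}), holm=True)
        assert (adj.pairwise.p.to_numpy()
                >= plain.pairwise.p.to_numpy() - 1e-15).all()
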