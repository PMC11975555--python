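"""Comparisons, ROC/AUC with the binormal oracle, Youden cutoff, trend test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tegcoag import biostats
from tegcoag.biostats import (
    DegenerateInputError,
    binormal_auc,
    bonferroni,
    compare_groups,
    empirical_auc,
    simulate_two_group_auc,
    trend_test,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    """Concordant-pair fraction (ties count half): the exhaustive oracle."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = len(pos) * len(neg)
    conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return conc / total


class TestCompareGroups:
    def test_mann_whitney_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(x, x, method="mann_whitney")
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_mann_whitney_exact_enumeration(self):
        # all 20 orderings of 3+3 values: separated samples give p = 2/20
        res = compare_groups([1, 2, 3], [4, 5, 6], method="mann_whitney")
        assert res.p_value == pytest.approx(0.1)

    def test_chi_square_on_printed_sex_table(self):
        res = compare_groups([[109, 49], [58, 51]], method="chi_square")
        assert res.p_value < 0.05

    def test_t_test_ci_covers_mean_difference(self, rng):
        x = rng.normal(1.0, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        res = compare_groups(x, y, method="t_test")
        lo, hi = res.ci_95
        assert lo < x.mean() - y.mean() < hi
        assert res.p_value < 0.01

    def test_t_test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([1.0, 1.0], [2.0, 2.0], method="t_test")

    def test_kruskal_wallis_three_groups(self, rng):
        groups = [rng.normal(m, 1, 40) for m in (0, 0, 2)]
        res = compare_groups(groups, method="kruskal_wallis")
        assert res.p_value < 0.01

    def test_bonferroni_adjustment(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], method="mann_whitney",
                             n_comparisons=6)
        assert res.adjusted_p == pytest.approx(min(1.0, 6 * res.p_value))
        assert bonferroni(0.3, 6) == 1.0


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([1, 2, 3], [0, 0, 1]).auc == 1.0

    def test_hand_counted_example(self):
        # 3 of 4 pos/neg pairs concordant
        assert empirical_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_matches_exhaustive_oracle_on_all_small_inputs(self):
        # every label pattern over small score vectors, including ties
        score_pool = [0.0, 1.0, 1.0, 2.0, 3.0, 3.0]
        for n in (3, 4, 6):
            scores = score_pool[:n]
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                expected = brute_force_auc(scores, labels)
                oriented = max(expected, 1 - expected)
                assert empirical_auc(scores, labels).auc == pytest.approx(oriented)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12),
           st.data())
    def test_oracle_property_random_small_inputs(self, scores, data):
        labels = data.draw(st.lists(st.booleans(), min_size=len(scores),
                                    max_size=len(scores)))
        labels = [int(b) for b in labels]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        raw = brute_force_auc(scores, labels)
        assert empirical_auc(scores, labels).auc == pytest.approx(
            max(raw, 1 - raw)
        )

    def test_orientation_flip_records_direction(self):
        res = empirical_auc([3, 2, 1], [0, 0, 1])  # lower score = positive
        assert res.auc == 1.0
        assert res.direction == "lower_is_positive"

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        a = empirical_auc(scores, labels).auc
        b = empirical_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            empirical_auc([1, 2, 3], [1, 1, 1])

    def test_delong_ci_brackets_auc_and_hanley_close(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 80), rng.normal(1, 1, 80)])
        labels = np.repeat([0, 1], 80)
        d = empirical_auc(scores, labels, ci_method="delong")
        h = empirical_auc(scores, labels, ci_method="hanley")
        assert d.auc_ci_95[0] <= d.auc <= d.auc_ci_95[1]
        assert abs(d.auc_ci_95[0] - h.auc_ci_95[0]) < 0.05


class TestBinormal:
    def test_identical_distributions(self):
        assert binormal_auc(0, 1, 0, 1) == 0.5

    def test_limit_of_separation(self):
        assert binormal_auc(0, 1, 100, 1) == pytest.approx(1.0)

    def test_printed_g_group_k(self):
        # K-value grade moments give ~0.728 (printed AUC: 0.731)
        assert binormal_auc(1.692, 0.553, 1.282, 0.390) == pytest.approx(
            0.728, abs=0.002
        )

    @pytest.mark.parametrize(
        "mu1, sd1, n1, mu2, sd2, n2",
        [
            (0.923, 1.513, 91, 2.267, 1.319, 67),   # CI, grade
            (1.692, 0.553, 91, 1.282, 0.390, 67),   # K, grade
            (66.841, 5.884, 91, 71.357, 4.195, 67),  # angle, grade
            (58.887, 6.046, 91, 63.054, 5.649, 67),  # MA, grade
            (4.309, 0.952, 158, 4.828, 1.126, 109),  # R, malignancy
        ],
    )
    def test_empirical_mean_matches_binormal_oracle(self, mu1, sd1, n1, mu2,
                                                    sd2, n2):
        sim = simulate_two_group_auc(mu1, sd1, n1, mu2, sd2, n2,
                                     n_replicates=200, seed=42)
        assert abs(sim - binormal_auc(mu1, sd1, mu2, sd2)) < 0.01


class TestYouden:
    def test_perfectly_separable(self):
        cutoff, sens, spec = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 2 < cutoff <= 3

    def test_exhaustive_scan_example(self):
        cutoff, sens, spec = youden_cutoff([1, 2, 3], [1, 0, 1])
        assert sens + spec - 1 == pytest.approx(0.5)

    def test_independent_labels_give_near_zero_j(self, rng):
        scores = rng.normal(size=4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        _, sens, spec = youden_cutoff(scores, labels)
        assert sens + spec - 1 < 0.1

    def test_ties_resolve_toward_higher_sensitivity(self):
        # J = 0.5 at cutoffs >=2 (sens 1.0) and >=4 (sens 0.5): pick >=2
        cutoff, sens, _ = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        assert cutoff == 2 and sens == 1.0


class TestTrend:
    def test_monotone_means_detected(self, rng):
        values = np.concatenate([rng.normal(m, 0.1, 30) for m in (0, 1, 2, 3)])
        labels = np.repeat(["g1", "g2", "g3", "g4"], 30)
        res = trend_test(values, labels, ordered_groups=["g1", "g2", "g3", "g4"])
        assert res.p_value < 1e-6
        assert res.extra["direction"] == "increasing"

    def test_generator_calibrated_ma_trend(self):
        # MA grade-group moments imply an increasing trend over benign/G-low/G-high
        rng = np.random.default_rng(0)
        values = np.concatenate([
            rng.normal(58.891, 5.811, 109),
            rng.normal(58.887, 6.046, 91),
            rng.normal(63.054, 5.649, 67),
        ])
        labels = np.repeat(["benign", "g_low", "g_high"], [109, 91, 67])
        res = trend_test(values, labels,
                         ordered_groups=["benign", "g_low", "g_high"])
        assert res.p_value < 0.01
        assert res.extra["direction"] == "increasing"

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 500
        for _ in range(reps):
            values = rng.normal(size=45)
            labels = np.repeat(["a", "b", "c"], 15)
            if trend_test(values, labels, ["a", "b", "c"]).p_value < 0.05:
                rejections += 1
        # binomial(500, 0.05): 3 sd band around 25
        assert abs(rejections - 0.05 * reps) < 3 * np.sqrt(reps * 0.05 * 0.95)

    def test_too_few_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            trend_test([1, 2, 3, 4], ["a", "a", "b", "b"], ["a", "b"])
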