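"""Selection and ROC machinery against enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from localrad import (
    FEATURE_NAMES,
    bonferroni_threshold,
    bootstrap_auc_ci,
    confusion_metrics,
    group_summary,
    roc_auc,
    select_feature,
    wilcoxon_rank_sum_one_tailed,
    youden_cutoff,
)
from localrad.global_features import FeatureMatrix

# ---------------------------------------------------------------- oracles


def oracle_rank_sum_p(x, y, direction):
    """Exhaustive permutation enumeration of the rank-sum distribution."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    sums = np.array([sum(c) for c in combinations(ranks, len(x))])
    if direction == "greater":
        return float((sums >= obs - 1e-9).mean())
    return float((sums <= obs + 1e-9).mean())


def oracle_auc(scores, labels):
    """Brute-force concordant-pair count (ties count 1/2)."""
    s = np.asarray(scores, float)
    pos = s[np.asarray(labels) == "TRG01"]
    neg = s[np.asarray(labels) == "TRG23"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def oracle_best_youden(scores, labels):
    """Exhaustive scan over every threshold between -inf and +inf."""
    s = np.asarray(scores, float)
    pos = np.asarray(labels) == "TRG01"
    cands = np.concatenate([[-np.inf], np.unique(s) + 1e-9, [np.inf]])
    best = -np.inf
    for c in cands:
        pred = s > c
        tp = (pred & pos).sum()
        fp = (pred & ~pos).sum()
        se = tp / pos.sum()
        sp = 1 - fp / (~pos).sum()
        best = max(best, se + sp - 1)
    return best


def labelled(n_pos, n_neg):
    return np.array(["TRG01"] * n_pos + ["TRG23"] * n_neg)


# ---------------------------------------------------------------- Wilcoxon


class TestWilcoxon:
    def test_fully_separated_three_vs_three(self):
        p = wilcoxon_rank_sum_one_tailed([1, 2, 3], [4, 5, 6], "less")
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_identical_samples_uninformative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum_one_tailed(x, x, "greater") >= 0.5
        assert wilcoxon_rank_sum_one_tailed(x, x, "less") >= 0.5

    def test_empty_or_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_one_tailed([1.0], [1, 2, 3], "greater")

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (2, 6), (4, 4), (5, 5), (6, 6), (4, 8)])
    @pytest.mark.parametrize("direction", ["greater", "less"])
    def test_exact_path_equals_enumeration(self, n1, n2, direction):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.normal(0.3, 1, n1)
            y = rng.normal(0.0, 1, n2)
            got = wilcoxon_rank_sum_one_tailed(x, y, direction)
            assert got == pytest.approx(oracle_rank_sum_p(x, y, direction), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(0.5, 1, 8)
            y = rng.normal(0.0, 1, 8)
            approx = scipy.stats.mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", use_continuity=True
            ).pvalue
            assert approx == pytest.approx(oracle_rank_sum_p(x, y, "greater"), abs=0.01)

    def test_ties_fall_back_to_corrected_approximation(self):
        x = [1, 1, 2, 2, 3]
        y = [2, 3, 3, 4, 4]
        p = wilcoxon_rank_sum_one_tailed(x, y, "less")
        assert 0 < p < 1


# ---------------------------------------------------------------- AUC


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([4, 5, 6, 1, 2, 3], labelled(3, 3)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.4, "TRG01", "TRG23")
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 10))
        n_neg = int(rng.integers(2, 11))
        scores = np.round(rng.normal(0, 1, n_pos + n_neg), 1)  # induces ties
        labels = labelled(n_pos, n_neg)
        assert roc_auc(scores, labels) == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )

    def test_adding_correctly_ordered_pair_never_decreases(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.normal(0, 1, 12)
            labels = labelled(5, 7)
            base = roc_auc(scores, labels)
            aug_scores = np.concatenate([scores, [scores.max() + 1, scores.min() - 1]])
            aug_labels = np.concatenate([labels, ["TRG01", "TRG23"]])
            assert roc_auc(aug_scores, aug_labels) >= base - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["TRG01", "TRG01"])


class TestBootstrapCi:
    def test_perfect_separation_upper_is_one(self):
        scores = [4, 5, 6, 1, 2, 3]
        lo, hi = bootstrap_auc_ci(scores, labelled(3, 3), reps=200, seed=1)
        assert hi == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 20)
        labels = labelled(8, 12)
        assert bootstrap_auc_ci(scores, labels, 300, seed=9) == bootstrap_auc_ci(
            scores, labels, 300, seed=9
        )

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            scores = np.concatenate([rng.normal(1, 1, 10), rng.normal(0, 1, 14)])
            labels = labelled(10, 14)
            lo, hi = bootstrap_auc_ci(scores, labels, 500, seed=2)
            assert lo <= roc_auc(scores, labels) <= hi


# ---------------------------------------------------------------- Youden


class TestYouden:
    def test_perfectly_separated(self):
        roc = youden_cutoff([4, 5, 6, 1, 2, 3], labelled(3, 3), bootstrap_reps=100)
        assert roc.youden == 1.0
        assert roc.sensitivity == roc.specificity == 1.0
        assert 3 < roc.cutoff < 4

    def test_paper_style_confusion_instance(self):
        """15 positives / 25 negatives with 3 FN and 3 FP at the optimum:
        SE = PPV = 80%, SP = NPV = 88%, YI = 0.68."""
        pos = [0.1, 1.1, 2.1] + [5.0 + 0.4 * k for k in range(12)]
        neg = [0.2 * k for k in range(22)] + [10.1, 10.3, 10.5]
        roc = youden_cutoff(pos + neg, labelled(15, 25), bootstrap_reps=100)
        assert (roc.tp, roc.fp, roc.tn, roc.fn) == (12, 3, 22, 3)
        assert roc.sensitivity == pytest.approx(0.80)
        assert roc.specificity == pytest.approx(0.88)
        assert roc.ppv == pytest.approx(0.80)
        assert roc.npv == pytest.approx(0.88)
        assert roc.youden == pytest.approx(0.68)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_exhaustive_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(3, 9))
        n_neg = int(rng.integers(3, 12))
        scores = np.round(rng.normal(0.4, 1, n_pos + n_neg), 1)
        labels = labelled(n_pos, n_neg)
        roc = youden_cutoff(scores, labels, bootstrap_reps=100, orient=False)
        assert roc.youden == pytest.approx(oracle_best_youden(scores, labels), abs=1e-12)
        roc.check_identities(n_pos, n_neg)

    def test_orientation_flip_recorded(self):
        # lower scores in the positive class: orientation must flip
        roc = youden_cutoff([1, 2, 3, 4, 5, 6], labelled(3, 3), bootstrap_reps=100)
        assert roc.flipped
        assert roc.auc == 1.0


# ---------------------------------------------------------------- selection


def matrix_from_values(values: np.ndarray, n_pos: int, n_neg: int) -> FeatureMatrix:
    frame = pd.DataFrame(values, columns=list(FEATURE_NAMES))
    frame.insert(0, "group", ["TRG01"] * n_pos + ["TRG23"] * n_neg)
    frame.insert(0, "patient_id", [f"p{i}" for i in range(n_pos + n_neg)])
    return FeatureMatrix(frame)


class TestSelectFeature:
    def test_single_signal_feature_recovered(self):
        """A cohort where exactly one feature carries signal: that feature
        is selected in >= 95% of seeded replicates."""
        hits = 0
        idx = list(FEATURE_NAMES).index("skewness_entropy")
        for rep in range(100):
            rng = np.random.default_rng(rep)
            values = rng.normal(0, 1, (40, 84))
            values[:15, idx] += 2.0
            sel = select_feature(matrix_from_values(values, 15, 25))
            hits += sel.selected_feature == "skewness_entropy"
        assert hits >= 95

    def test_identical_groups_give_empty_selection(self):
        values = np.tile(np.linspace(0, 1, 84), (10, 1))
        sel = select_feature(matrix_from_values(values, 5, 5))
        assert sel.selected_feature is None
        assert sel.m_tests == 0
        assert sel.ratio_r is None
        assert not any(t.passed_step1 for t in sel.per_feature)

    def test_bonferroni_and_ratio_bookkeeping(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (40, 84))
        values[:15, 5] += 3.0
        sel = select_feature(matrix_from_values(values, 15, 25))
        m = sel.m_tests
        assert m == sum(t.passed_step1 for t in sel.per_feature)
        for t in sel.survivors:
            assert t.p_bonferroni == pytest.approx(min(1.0, t.p_value * m))
        assert sel.n_smallest_class == 15
        assert sel.n_features_selected == 1
        assert sel.ratio_r == 15.0
        assert sel.threshold == pytest.approx(0.05 / m)
        best = min((t for t in sel.per_feature if t.passed_step1), key=lambda t: t.p_value)
        assert sel.selected_feature == best.feature_name

    def test_m_correction_all(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (30, 84))
        values[:10, 0] += 3.0
        sel = select_feature(matrix_from_values(values, 10, 20), m_correction="all")
        assert sel.m_tests == 84

    def test_too_small_group_rejected(self):
        values = np.random.default_rng(0).normal(size=(3, 84))
        with pytest.raises(ValueError):
            select_feature(matrix_from_values(values, 1, 2))


# ---------------------------------------------------------------- summaries


class TestSummaries:
    def test_three_point_group(self):
        scores = [4.00, 4.08, 4.15, 3.0, 3.5]
        out = group_summary(scores, labelled(3, 2))
        assert out["TRG01"]["median"] == pytest.approx(4.08)
        # linear-interpolation quartiles: Q1 = 4.04, Q3 = 4.115
        assert out["TRG01"]["iqr"] == pytest.approx(0.075)

    def test_single_element_group_iqr_zero(self):
        out = group_summary([4.0, 1.0, 2.0], labelled(1, 2))
        assert out["TRG01"]["iqr"] == 0.0
        assert out["TRG01"]["n"] == 1

    def test_matches_independent_quantile_implementation(self, rng):
        for _ in range(10):
            scores = rng.normal(0, 2, 30)
            labels = labelled(12, 18)
            out = group_summary(scores, labels)
            pos = scores[:12]
            assert out["TRG01"]["iqr"] == pytest.approx(
                scipy.stats.iqr(pos, interpolation="linear"), abs=1e-12
            )
            assert out["TRG01"]["median"] == pytest.approx(np.median(pos))

    def test_confusion_metrics_identities(self):
        m = confusion_metrics(12, 3, 22, 3)
        assert m["sensitivity"] == pytest.approx(0.80)
        assert m["specificity"] == pytest.approx(0.88)
        assert m["youden"] == pytest.approx(m["sensitivity"] + m["specificity"] - 1)

    def test_bonferroni_threshold(self):
        assert bonferroni_threshold(0.05, 18) == pytest.approx(0.05 / 18)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
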