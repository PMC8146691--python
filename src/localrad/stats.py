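"""Univariate feature selection and ROC / Youden evaluation.

The selection follows a three-step procedure: (1) discard features whose
one-tailed Wilcoxon rank-sum p-value is not below alpha, (2) rank the
survivors by Bonferroni-corrected p-value, (3) select the minimum.  The
selected feature is then assessed with a ROC curve (AUC with a stratified
percentile-bootstrap CI) and a Youden-index optimal cut-off with the full
confusion-matrix arithmetic (sensitivity, specificity, PPV, NPV).

Positives are the responders (TRG0-1); score orientation is auto-detected
(flipped when AUC < 0.5, and the flip recorded), so that a higher score
always means "more responder-like" at evaluation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .global_features import FEATURE_NAMES, GROUP_LABELS, FeatureMatrix

__all__ = [
    "wilcoxon_rank_sum_one_tailed",
    "select_feature",
    "roc_auc",
    "bootstrap_auc_ci",
    "youden_cutoff",
    "group_summary",
    "confusion_metrics",
    "bonferroni_threshold",
    "UnivariateSelection",
    "RocAnalysis",
    "FeatureTest",
]

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 16  # exact rank-sum enumeration up to this combined sample size


@dataclass
class FeatureTest:
    """One feature's univariate test result."""

    feature_name: str
    p_value: float
    direction: str  # alternative actually tested: 'greater' or 'less'
    passed_step1: bool
    p_bonferroni: float | None = None
    rank: int | None = None


@dataclass
class UnivariateSelection:
    """Outcome of the three-step univariate selection."""

    per_feature: list[FeatureTest]
    m_tests: int
    selected_feature: str | None
    alpha: float
    n_smallest_class: int
    n_features_selected: int
    ratio_r: float | None

    @property
    def threshold(self) -> float | None:
        """Effective Bonferroni significance threshold alpha / m."""
        return bonferroni_threshold(self.alpha, self.m_tests) if self.m_tests else None

    @property
    def survivors(self) -> list[FeatureTest]:
        return sorted(
            (t for t in self.per_feature if t.passed_step1), key=lambda t: t.rank
        )


@dataclass
class RocAnalysis:
    """ROC summary of one score: AUC, bootstrap CI and Youden operating point."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    youden: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    flipped: bool = False  # True if scores were negated to orient AUC >= 0.5

    def check_identities(self, n_pos: int, n_neg: int) -> None:
        """Recompute the confusion identities; raise if any is violated."""
        if self.tp + self.fn != n_pos or self.tn + self.fp != n_neg:
            raise AssertionError("confusion counts do not partition the classes")
        m = confusion_metrics(self.tp, self.fp, self.tn, self.fn)
        for key in ("sensitivity", "specificity", "ppv", "npv", "youden"):
            if not math.isclose(getattr(self, key), m[key], abs_tol=1e-12):
                raise AssertionError(f"{key} inconsistent with confusion counts")


def wilcoxon_rank_sum_one_tailed(x, y, direction: str) -> float:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``direction='greater'`` tests the alternative that ``x`` tends larger
    than ``y``.  Exact enumeration is used for combined samples of at most
    16 without ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=direction, method=method, use_continuity=True)
    return float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0))


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def select_feature(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    *,
    m_correction: str = "survivors",
) -> UnivariateSelection:
    """Three-step univariate selection over the 84 features.

    The one-tailed direction of each feature's test is set by the sign of
    its group-median difference on the data itself (a post-hoc choice that
    inflates the type-I error; logged as a warning).  ``m_correction`` sets
    the Bonferroni multiplicity to the number of step-1 survivors
    (``"survivors"``, default) or to all 84 tests (``"all"``).

    An empty selection (no survivor) is a valid result, not an exception.
    """
    pos_all, neg_all = matrix.group_values(FEATURE_NAMES[0])
    if pos_all.size < 2 or neg_all.size < 2:
        raise ValueError("each group needs at least 2 patients")
    logger.warning(
        "one-tailed directions chosen from the observed median differences; "
        "this post-hoc choice inflates the type-I error"
    )
    tests: list[FeatureTest] = []
    for name in FEATURE_NAMES:
        pos, neg = matrix.group_values(name)
        direction = "greater" if np.median(pos) >= np.median(neg) else "less"
        p = wilcoxon_rank_sum_one_tailed(pos, neg, direction)
        tests.append(
            FeatureTest(
                feature_name=name,
                p_value=p,
                direction=direction,
                passed_step1=p < alpha,
            )
        )
    survivors = [t for t in tests if t.passed_step1]
    m = len(survivors) if m_correction == "survivors" else len(FEATURE_NAMES)
    order = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for t in survivors:
        t.p_bonferroni = min(1.0, t.p_value * m)
    ranked = sorted(
        survivors, key=lambda t: (t.p_bonferroni, t.p_value, order[t.feature_name])
    )
    for i, t in enumerate(ranked):
        t.rank = i + 1
    n_smallest = int(min(pos_all.size, neg_all.size))
    selected = ranked[0].feature_name if ranked else None
    l = 1 if selected else 0
    return UnivariateSelection(
        per_feature=tests,
        m_tests=m if survivors else 0,
        selected_feature=selected,
        alpha=alpha,
        n_smallest_class=n_smallest,
        n_features_selected=l,
        ratio_r=(n_smallest / l) if l else None,
    )


def _check_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    pos = lab == GROUP_LABELS[0]
    neg = lab == GROUP_LABELS[1]
    if not (pos | neg).all():
        raise ValueError(f"labels must be in {GROUP_LABELS}")
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos


def roc_auc(scores, labels) -> float:
    """AUC by the Mann-Whitney pair-concordance formula (ties count 1/2).

    Positives are TRG01; higher scores are treated as more positive.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _check_labels(labels)
    ranks = sps.rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(
    scores, labels, reps: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Patients are resampled with replacement within each class, so every
    resample keeps both classes; the CI is the percentile interval of the
    bootstrap AUC distribution.  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    scores = np.asarray(scores, dtype=float)
    pos = _check_labels(labels)
    sp, sn = scores[pos], scores[~pos]
    n_pos, n_neg = sp.size, sn.size
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    for i in range(reps):
        bp = sp[rng.integers(0, n_pos, n_pos)]
        bn = sn[rng.integers(0, n_neg, n_neg)]
        ranks = sps.rankdata(np.concatenate([bp, bn]))
        u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
        aucs[i] = u / (n_pos * n_neg)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and Youden index from counts."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": tp / (tp + fp) if tp + fp else 0.0,
        "npv": tn / (tn + fn) if tn + fn else 0.0,
        "youden": sens + spec - 1.0,
    }


def youden_cutoff(
    scores,
    labels,
    *,
    bootstrap_reps: int = 2000,
    seed: int = 0,
    orient: bool = True,
) -> RocAnalysis:
    """Youden-index optimal cut-off and full ROC summary.

    Candidate cut-offs are the midpoints between consecutive distinct
    sorted scores plus -inf and +inf; a patient is called positive when the
    (possibly orientation-flipped) score exceeds the cut-off.  Ties in the
    Youden index are broken toward higher sensitivity (never exclude a
    responder unnecessarily), then toward the lower cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _check_labels(labels)
    auc = roc_auc(scores, labels)
    flipped = False
    if orient and auc < 0.5:
        scores = -scores
        auc = 1.0 - auc
        flipped = True
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
    )
    best = None
    for c in candidates:
        pred = scores > c
        tp = int((pred & pos).sum())
        fp = int((pred & ~pos).sum())
        fn = int((~pred & pos).sum())
        tn = int((~pred & ~pos).sum())
        m = confusion_metrics(tp, fp, tn, fn)
        key = (m["youden"], m["sensitivity"], -c)
        if best is None or key > best[0]:
            best = (key, c, tp, fp, tn, fn, m)
    _, cutoff, tp, fp, tn, fn, m = best
    lo, hi = bootstrap_auc_ci(
        -scores if flipped else scores, labels, reps=bootstrap_reps, seed=seed
    )
    if flipped:
        lo, hi = 1.0 - hi, 1.0 - lo
    result = RocAnalysis(
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=float(cutoff),
        youden=m["youden"],
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        ppv=m["ppv"],
        npv=m["npv"],
        flipped=flipped,
    )
    result.check_identities(int(pos.sum()), int((~pos).sum()))
    return result


def group_summary(scores, labels) -> dict[str, dict[str, float]]:
    """Median, quartiles and IQR per group (linear-interpolation quantiles)."""
    scores = np.asarray(scores, dtype=float)
    pos = _check_labels(labels)
    out = {}
    for label, sel in zip(GROUP_LABELS, (pos, ~pos)):
        v = scores[sel]
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        out[label] = {
            "n": int(v.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(q3 - q1),
        }
    return out
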