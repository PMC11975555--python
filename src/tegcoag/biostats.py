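"""Group-comparison statistics and ROC analysis for coagulation markers.

The discrimination question throughout is binary: does a TEG parameter (or a
conventional coagulation index) separate benign from malignant tumors, early
from late TNM stage, or low from high histologic grade?  AUCs are computed by
the rank (Mann-Whitney) formulation with midranks for ties, oriented so the
reported AUC is at least 0.5, with DeLong confidence intervals.  A closed-form
binormal AUC serves as the analytic oracle when both classes are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "RocResult",
    "DegenerateInputError",
    "compare_groups",
    "empirical_auc",
    "binormal_auc",
    "youden_cutoff",
    "trend_test",
    "bonferroni",
    "roc_curve_table",
    "simulate_two_group_auc",
]


class DegenerateInputError(ValueError):
    """Raised when a test's input admits no meaningful statistic."""


@dataclass(frozen=True)
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    ci_95: tuple | None = None
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted_p must be >= p_value")


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_95: tuple
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # higher_is_positive | lower_is_positive
    p_value: float | None = None

    def __post_init__(self):
        lo, hi = self.auc_ci_95
        if not (lo <= self.auc + 1e-12 and self.auc <= hi + 1e-12):
            raise ValueError("AUC must lie inside its confidence interval")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_95": list(self.auc_ci_95),
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "direction": self.direction,
            "p_value": self.p_value,
        }


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value for m comparisons."""
    return float(min(1.0, m * p))


# ---------------------------------------------------------------------------
# Two-group and k-group comparisons
# ---------------------------------------------------------------------------


def _exact_mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments.

    Handles ties via midranks; feasible for combined n <= 12 (<= 924 splits).
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return float(u_obs), count / total


def compare_groups(x, y=None, method: str = "t_test",
                   n_comparisons: int | None = None) -> ComparisonResult:
    """Two-group (or k-group) comparison.

    ``method``:
      * ``t_test`` — two-sample Student t with 95% CI of the mean difference.
      * ``mann_whitney`` — exact enumeration for combined n <= 12, otherwise
        normal approximation with midranks and continuity correction.
      * ``chi_square`` — ``x`` is a 2x2 (or r x c) count table; Pearson chi2.
      * ``kruskal_wallis`` — ``x`` is a sequence of >= 2 samples.

    ``n_comparisons`` attaches a Bonferroni-adjusted p-value.
    """
    if method == "chi_square":
        table = np.asarray(x, dtype=float)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        res = ComparisonResult("chi_square", float(chi2), float(p))
    elif method == "kruskal_wallis":
        samples = [np.asarray(s, dtype=float) for s in x]
        if len(samples) < 2:
            raise DegenerateInputError("kruskal_wallis needs >= 2 samples")
        stat, p = stats.kruskal(*samples)
        res = ComparisonResult("kruskal_wallis", float(stat), float(p))
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise DegenerateInputError("samples must be non-empty")
        if method == "t_test":
            if np.var(x) == 0 and np.var(y) == 0:
                raise DegenerateInputError("zero variance in both samples")
            stat, p = stats.ttest_ind(x, y, equal_var=True)
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) \
                / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
            diff = x.mean() - y.mean()
            res = ComparisonResult(
                "t_test", float(stat), float(p),
                ci_95=(float(diff - tcrit * se), float(diff + tcrit * se)),
            )
        elif method == "mann_whitney":
            if len(x) + len(y) <= 12:
                u, p = _exact_mann_whitney(x, y)
            else:
                u, p = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic",
                    use_continuity=True,
                )
            res = ComparisonResult("mann_whitney", float(u), float(p))
        else:
            raise ValueError(f"unknown method {method!r}")
    if n_comparisons is not None:
        res = ComparisonResult(
            res.method, res.statistic, res.p_value, res.ci_95,
            adjusted_p=bonferroni(res.p_value, n_comparisons), extra=res.extra,
        )
    return res


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank formulation (equals the tie-corrected concordance)."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc**2)
            + (n - 1) * (q2 - auc**2)) / (m * n)


def empirical_auc(scores, labels, ci_method: str = "delong") -> RocResult:
    """Oriented empirical AUC with confidence interval and Youden cutoff.

    If the raw AUC is below 0.5 the score direction flips
    (``lower_is_positive``) and AUC := 1 - AUC, matching how diagnostic
    tables report discrimination.  The p-value tests AUC = 0.5 using the
    DeLong standard error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2 or set(classes) != {0, 1}:
        raise DegenerateInputError("labels must contain both classes (0/1)")
    auc_raw = _midrank_auc(scores, labels)
    direction = "higher_is_positive"
    oriented = scores
    if auc_raw < 0.5:
        direction = "lower_is_positive"
        oriented = -scores
    auc = max(auc_raw, 1 - auc_raw)
    m = int(labels.sum())
    n = len(labels) - m
    if ci_method == "delong":
        var = _delong_variance(oriented, labels)
    elif ci_method == "hanley":
        var = _hanley_mcneil_variance(auc, m, n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    p = 1.0 if se == 0 and auc == 0.5 else float(
        2 * stats.norm.sf(abs(auc - 0.5) / se) if se > 0 else 0.0
    )
    cutoff, sens, spec = youden_cutoff(oriented, labels)
    if direction == "lower_is_positive":
        cutoff = -cutoff  # report on the original score scale (<= cutoff positive)
    return RocResult(
        auc=float(auc), auc_ci_95=(lo, hi), cutoff=float(cutoff),
        sensitivity=float(sens), specificity=float(spec),
        direction=direction, p_value=p,
    )


def binormal_auc(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Closed-form AUC for two Gaussian classes: Phi(|mu2-mu1| / sqrt(sd1^2+sd2^2)).

    Analytic oracle for the empirical AUC when class scores are Gaussian.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf(abs(mu2 - mu1) / np.hypot(sd1, sd2)))


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Predicts positive when score >= cutoff; candidate cutoffs are the observed
    score values.  Ties in J resolve toward the cutoff with higher
    sensitivity (the lower threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise DegenerateInputError("labels must contain both classes")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[2] + 1e-12
        ):
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec)


def roc_curve_table(scores, labels) -> "np.ndarray":
    """(fpr, tpr, threshold) triples over all observed thresholds, for export."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        pred = scores >= t
        tpr = np.sum(pred & (labels == 1)) / n_pos
        fpr = np.sum(pred & (labels == 0)) / n_neg
        rows.append((fpr, tpr, t))
    return np.asarray(rows)


def simulate_two_group_auc(mu1, sd1, n1, mu2, sd2, n2,
                           n_replicates: int = 500, seed: int = 0) -> float:
    """Mean oriented empirical AUC over replicate two-Gaussian cohorts.

    Replays the published per-group Gaussian moments and sample sizes: each
    replicate draws group scores from N(mu1, sd1^2) (n1) and N(mu2, sd2^2)
    (n2), labels the second group positive, and computes the oriented
    empirical AUC; the mean over replicates is returned.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    aucs = np.empty(n_replicates)
    for i in range(n_replicates):
        scores = np.concatenate([
            rng.normal(mu1, sd1, n1), rng.normal(mu2, sd2, n2)
        ])
        auc_raw = _midrank_auc(scores, labels)
        aucs[i] = max(auc_raw, 1 - auc_raw)
    return float(aucs.mean())


# ---------------------------------------------------------------------------
# Ordered-group trend
# ---------------------------------------------------------------------------


def trend_test(values, group_labels, ordered_groups=None) -> ComparisonResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    ``ordered_groups`` gives the group order (defaults to sorted unique
    labels).  The statistic sums pairwise Mann-Whitney counts over ordered
    group pairs; the p-value is two-sided from the tie-corrected normal
    approximation.  ``extra`` carries the Kruskal-Wallis companion test and
    Bonferroni-adjusted pairwise Mann-Whitney p-values.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if ordered_groups is None:
        ordered_groups = sorted(np.unique(group_labels).tolist())
    if len(ordered_groups) < 3:
        raise DegenerateInputError("trend test needs >= 3 ordered groups")
    samples = [values[group_labels == g] for g in ordered_groups]
    if any(len(s) == 0 for s in samples):
        raise DegenerateInputError("every ordered group must be non-empty")

    jt = 0.0
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            jt += np.sum(b[:, None] > a[None, :]) + 0.5 * np.sum(
                b[:, None] == a[None, :]
            )
    ns = np.array([len(s) for s in samples], dtype=float)
    n = ns.sum()
    mean_jt = (n**2 - np.sum(ns**2)) / 4
    # tie-corrected null variance
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    var = (
        (n * (n - 1) * (2 * n + 5) - np.sum(ns * (ns - 1) * (2 * ns + 5))
         - np.sum(t * (t - 1) * (2 * t + 5))) / 72
        + np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
        / (36 * n * (n - 1) * (n - 2))
        + np.sum(ns * (ns - 1)) * np.sum(t * (t - 1)) / (8 * n * (n - 1))
    )
    if var <= 0:
        raise DegenerateInputError("degenerate trend input (all values tied)")
    z = (jt - mean_jt) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))

    kw = compare_groups(samples, method="kruskal_wallis")
    pairs = {}
    m = len(samples) * (len(samples) - 1) // 2
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            r = compare_groups(samples[i], samples[j], method="mann_whitney",
                               n_comparisons=m)
            pairs[f"{ordered_groups[i]} vs {ordered_groups[j]}"] = r.adjusted_p
    return ComparisonResult(
        method="jonckheere_terpstra", statistic=float(jt), p_value=p,
        extra={
            "z": float(z),
            "direction": "increasing" if z > 0 else "decreasing",
            "kruskal_wallis_p": kw.p_value,
            "pairwise_adjusted_p": pairs,
        },
    )
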