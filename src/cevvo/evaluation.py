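"""Cross-validation fold construction and performance assessment.

Implements the patient-level fold plan (groups with fixed success/failure
quotas, surplus patients excluded at random, the test group rotating over all
positions), AUROC / average precision with percentile-bootstrap confidence
intervals, per-day metric tables bucketed by each sample's end time, and the
paired sign-flip permutation test used to compare two classifiers scored on the
same samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = [
    "FoldPlan", "MetricCI", "make_real_folds", "auroc", "average_precision",
    "bootstrap_ci", "per_day_metrics", "pooled_window_metric",
    "paired_permutation_test",
]


def auroc(labels, scores) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney U statistic.

    Computed from average ranks, so ties count one half.  This rank form is
    used (rather than a curve integration) because the bootstrap and
    permutation procedures evaluate it hundreds of thousands of times; the
    suite checks it against both a brute-force pairwise oracle and sklearn.
    """
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC is undefined when only one class is present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def average_precision(labels, scores) -> float:
    """Average precision (stepwise area under the precision-recall curve)."""
    y = np.asarray(labels)
    if y.sum() < 1:
        raise ValueError("average precision is undefined without positives")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


_METRICS: dict[str, Callable] = {"auroc": auroc, "average_precision": average_precision}


def _resolve_metric(metric) -> Callable:
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected one of "
                         f"{tuple(_METRICS)} or a callable") from None


@dataclass
class MetricCI:
    """A point estimate with a percentile-bootstrap confidence interval."""

    point: float
    lower: float
    upper: float
    B: int
    alpha: float
    n_skipped: int = 0

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class FoldPlan:
    """Patient-level group assignment for one cross-validation iteration."""

    iteration: int
    groups: list                       # n_groups disjoint lists of patient ids
    excluded: list
    composition: tuple                 # (n_success, n_fail) per group

    def splits(self):
        """Rotate the test group over all positions -> (train, val, test) ids."""
        n = len(self.groups)
        for k in range(n):
            test = list(self.groups[k])
            val = list(self.groups[(k + 1) % n])
            train = [pid for i, g in enumerate(self.groups)
                     if i not in (k, (k + 1) % n) for pid in g]
            yield train, val, test


def make_real_folds(ids: Sequence[str], labels: Sequence[int], n_iter: int = 12,
                    rng: np.random.Generator | None = None, n_groups: int = 5,
                    n_success_per_group: int = 18, n_fail_per_group: int = 5,
                    ) -> list[FoldPlan]:
    """Build ``n_iter`` randomized fold plans with fixed per-group quotas.

    Each iteration shuffles the cohort, fills ``n_groups`` disjoint groups with
    exactly ``n_success_per_group`` successes and ``n_fail_per_group`` failures
    and excludes the surplus at random (a 90/28 cohort yields 5 groups of
    18 + 5 = 23 patients with 3 excluded).
    """
    rng = np.random.default_rng() if rng is None else rng
    ids = np.asarray(ids, dtype=object)
    labels = np.asarray(labels)
    succ = ids[labels == 1]
    fail = ids[labels == 0]
    need_s = n_groups * n_success_per_group
    need_f = n_groups * n_fail_per_group
    if succ.size < need_s or fail.size < need_f:
        raise ValueError(
            f"cohort too small for the quota: need {need_s} successes and "
            f"{need_f} failures, have {succ.size} and {fail.size}")
    plans = []
    for it in range(n_iter):
        s = list(rng.permutation(succ))
        f = list(rng.permutation(fail))
        groups = [s[g * n_success_per_group:(g + 1) * n_success_per_group]
                  + f[g * n_fail_per_group:(g + 1) * n_fail_per_group]
                  for g in range(n_groups)]
        plans.append(FoldPlan(
            iteration=it + 1, groups=groups,
            excluded=s[need_s:] + f[need_f:],
            composition=(n_success_per_group, n_fail_per_group)))
    return plans


def _is_degenerate(y_res, metric_fn) -> bool:
    if metric_fn is average_precision:
        return y_res.sum() < 1
    return np.unique(y_res).size < 2


def bootstrap_ci(labels, scores, metric="auroc", B: int = 5000,
                 alpha: float = 0.05, rng: np.random.Generator | None = None,
                 ) -> MetricCI:
    """Percentile bootstrap CI: resample (label, score) pairs jointly B times.

    Resamples where the metric is undefined (single-class for AUROC, no
    positives for AP) are skipped and counted in ``n_skipped``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    metric_fn = _resolve_metric(metric)
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    # canonical pair order makes the CI invariant to input ordering under a
    # fixed generator
    order = np.lexsort((y, s))
    y, s = y[order], s[order]
    n = y.size
    point = metric_fn(y, s)
    values, skipped = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if _is_degenerate(y[idx], metric_fn):
            skipped += 1
            continue
        values.append(metric_fn(y[idx], s[idx]))
    if not values:
        raise ValueError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricCI(point=float(point), lower=float(lo), upper=float(hi),
                    B=B, alpha=alpha, n_skipped=skipped)


def per_day_metrics(predictions, max_day: int = 24, metric="auroc",
                    B: int = 5000, alpha: float = 0.05,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Metric + CI per one-day bucket of sample end times.

    A sample whose truncation ends at day ``e`` falls in bucket
    ``d = ceil(e)``, i.e. buckets are the half-open intervals (d-1, d] for
    d = 1..max_day (an end time of exactly 0 also lands on day 1).  Buckets
    that are empty or where the metric is undefined report NaN.
    """
    rng = np.random.default_rng() if rng is None else rng
    metric_fn = _resolve_metric(metric)
    end_days = np.array([p.end_day for p in predictions])
    y = np.array([p.label for p in predictions])
    s = np.array([p.score for p in predictions])
    rows = []
    for d in range(1, max_day + 1):
        mask = (end_days > d - 1) & (end_days <= d) if d > 1 \
            else (end_days <= 1)
        row = {"day": d, "n": int(mask.sum()),
               "value": np.nan, "lower": np.nan, "upper": np.nan}
        if mask.sum() > 0 and not _is_degenerate(y[mask], metric_fn):
            ci = bootstrap_ci(y[mask], s[mask], metric_fn, B=B, alpha=alpha,
                              rng=rng)
            row.update(value=ci.point, lower=ci.lower, upper=ci.upper)
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_window_metric(predictions, day_min: float, day_max: float,
                         metric="auroc", B: int = 5000, alpha: float = 0.05,
                         rng: np.random.Generator | None = None) -> MetricCI:
    """Metric + CI over all samples with end time in (day_min, day_max]."""
    sel = [p for p in predictions if day_min < p.end_day <= day_max]
    return bootstrap_ci([p.label for p in sel], [p.score for p in sel],
                        metric, B=B, alpha=alpha, rng=rng)


def paired_permutation_test(scores_a, scores_b, labels, metric="auroc",
                            n_perm: int = 10000,
                            rng: np.random.Generator | None = None,
                            exhaustive: bool | None = None) -> float:
    """Two-sided paired permutation test for metric(a) - metric(b).

    The null distribution swaps ``a_i`` and ``b_i`` independently with
    probability 1/2 per sample.  Monte-Carlo p-values use the add-one
    correction p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1); with
    ``exhaustive=True`` (the default for n <= 20 when 2^n <= n_perm) all 2^n
    swap patterns are enumerated and the p-value is exact.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be equal-length")
    metric_fn = _resolve_metric(metric)
    n = a.size
    stat = metric_fn(y, a) - metric_fn(y, b)
    if exhaustive is None:
        exhaustive = n <= 20 and 2 ** n <= n_perm
    tol = 1e-12
    if exhaustive:
        hits = 0
        for code in range(2 ** n):
            mask = (code >> np.arange(n)) & 1 == 1
            a_p = np.where(mask, b, a)
            b_p = np.where(mask, a, b)
            if abs(metric_fn(y, a_p) - metric_fn(y, b_p)) >= abs(stat) - tol:
                hits += 1
        return hits / 2 ** n
    rng = np.random.default_rng() if rng is None else rng
    hits = 0
    for _ in range(n_perm):
        mask = rng.random(n) < 0.5
        a_p = np.where(mask, b, a)
        b_p = np.where(mask, a, b)
        if abs(metric_fn(y, a_p) - metric_fn(y, b_p)) >= abs(stat) - tol:
            hits += 1
    return (1 + hits) / (n_perm + 1)
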