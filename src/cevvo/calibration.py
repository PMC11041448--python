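"""Probability calibration, risk grouping and the exact group comparison test.

Raw sigmoid scores are recalibrated with Platt scaling (a logistic fit of the
outcome on the log-odds of the raw score, preserving rank order).  Calibrated
training scores define four risk groups from their mean M and SD S:

    group 0 (high risk):  x <= M - S
    group 1:              M - S < x <= M
    group 2:              M < x <= M + S
    group 3 (low risk):   M + S < x

Patients are snapshot at a clinical horizon (72 or 96 h) by taking their latest
prediction at or before the horizon, excluding patients decannulated earlier.
Success proportions between two groups are compared with Boschloo's exact
unconditional test (Fisher's one-sided exact p as the ordering statistic,
maximized over a grid of nuisance success probabilities), which is uniformly at
least as powerful as Fisher's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PlattParams", "RiskGrouping", "fit_platt", "apply_platt",
    "calibration_curve", "assign_risk_group", "fit_risk_grouping",
    "snapshot_at_hours", "boschloo_exact", "fisher_one_sided",
]

_EPS = 1e-7


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


@dataclass
class PlattParams:
    """Slope/intercept of the calibration sigmoid, fitted on training scores."""

    A: float
    B: float
    fitted_on: str = "train"


def fit_platt(raw_scores, labels, fitted_on: str = "train") -> PlattParams:
    """Fit Platt scaling: logistic regression of labels on logit(raw score)."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("Platt scaling needs both classes in the labels")
    z = _logit(raw_scores).reshape(-1, 1)
    lr = LogisticRegression(C=1e6, max_iter=5000)
    lr.fit(z, y)
    return PlattParams(A=float(lr.coef_[0, 0]), B=float(lr.intercept_[0]),
                       fitted_on=fitted_on)


def apply_platt(params: PlattParams, raw_scores) -> np.ndarray:
    """Calibrated score = sigmoid(A * logit(raw) + B); monotone in the raw score."""
    z = params.A * _logit(raw_scores) + params.B
    return 1.0 / (1.0 + np.exp(-z))


def calibration_curve(scores, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table: per-bin mean prediction, observed rate and count.

    Bins are equal-width on [0, 1], half-open [l, u) with the final bin closed;
    empty bins are reported with count 0 and NaN statistics.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.arange(n_bins + 1) / n_bins  # exact k/n doubles
    idx = np.clip(np.digitize(s, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append({
            "bin_lower": edges[b], "bin_upper": edges[b + 1], "count": n,
            "mean_score": float(s[mask].mean()) if n else np.nan,
            "observed_rate": float(y[mask].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)


def assign_risk_group(x, M: float, S: float):
    """Map calibrated score(s) to risk group 0-3 from the training mean/SD."""
    if S < 0:
        raise ValueError("S must be >= 0")
    x = np.asarray(x, dtype=float)
    group = np.select(
        [x <= M - S, x <= M, x <= M + S],
        [0, 1, 2],
        default=3,
    )
    return group if group.ndim else int(group)


@dataclass
class RiskGrouping:
    """Training-set calibration statistics plus the group-assignment rule."""

    platt: PlattParams
    M: float
    S: float

    def calibrate(self, raw_scores) -> np.ndarray:
        return apply_platt(self.platt, raw_scores)

    def group(self, raw_scores):
        return assign_risk_group(self.calibrate(raw_scores), self.M, self.S)


def fit_risk_grouping(train_raw_scores, train_labels) -> RiskGrouping:
    """Fit Platt scaling and the group thresholds on training predictions."""
    platt = fit_platt(train_raw_scores, train_labels)
    cal = apply_platt(platt, train_raw_scores)
    return RiskGrouping(platt=platt, M=float(cal.mean()), S=float(cal.std()))


def snapshot_at_hours(predictions: Sequence, run_hours: dict, hours: float,
                      grouping: RiskGrouping | None = None) -> pd.DataFrame:
    """Per-patient snapshot: the latest prediction at or before ``hours``.

    ``run_hours`` maps patient id to total run length; patients whose run is
    shorter than the horizon (decannulated before it) are excluded, as are
    patients with no prediction before the horizon (with a warning).  If a
    fitted :class:`RiskGrouping` is given, calibrated scores and groups are
    included.
    """
    rows = []
    by_patient: dict[str, list] = {}
    for p in predictions:
        by_patient.setdefault(p.patient_id, []).append(p)
    for pid, preds in by_patient.items():
        if run_hours[pid] < hours:
            continue  # decannulated before the horizon
        eligible = [p for p in preds if p.end_day * 24.0 <= hours]
        if not eligible:
            warnings.warn(f"patient {pid}: no prediction before {hours} h; "
                          "excluded from the snapshot", stacklevel=2)
            continue
        best = max(eligible, key=lambda p: p.end_day)
        rows.append({"patient_id": pid, "score": best.score,
                     "end_hours": best.end_day * 24.0, "label": best.label})
    df = pd.DataFrame(rows, columns=["patient_id", "score", "end_hours", "label"])
    if grouping is not None and len(df):
        df["calibrated"] = grouping.calibrate(df["score"].to_numpy())
        df["group"] = grouping.group(df["score"].to_numpy())
    return df


def fisher_one_sided(table) -> float:
    """Fisher's exact one-sided p that row 0's success probability is lower."""
    (s0, f0), (s1, f1) = np.asarray(table, dtype=int)
    n0, n1 = s0 + f0, s1 + f1
    total_s = s0 + s1
    return float(hypergeom.cdf(s0, n0 + n1, total_s, n0))


def boschloo_exact(table, alternative: str = "less", grid_size: int = 999,
                   ) -> float:
    """Boschloo's exact unconditional test on a 2x2 table of [success, failure].

    ``alternative="less"``: row 0's success probability is smaller than row
    1's (``"greater"`` swaps the rows; ``"two-sided"`` doubles the smaller
    one-sided p, capped at 1).  The ordering statistic is Fisher's one-sided
    exact p; the p-value maximizes, over a grid of ``grid_size`` nuisance
    success probabilities in (0, 1), the probability under independent
    binomials of observing a table with Fisher p at most the observed one.
    Always <= Fisher's p for the same one-sided alternative.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2: [[s0, f0], [s1, f1]]")
    if (tab < 0).any():
        raise ValueError("table counts must be non-negative")
    if (tab.sum(axis=1) < 1).any():
        raise ValueError("both groups must contain at least one observation")
    if alternative == "greater":
        return boschloo_exact(tab[::-1], "less", grid_size)
    if alternative == "two-sided":
        p = 2.0 * min(boschloo_exact(tab, "less", grid_size),
                      boschloo_exact(tab[::-1], "less", grid_size))
        return min(1.0, p)
    if alternative != "less":
        raise ValueError("alternative must be 'less', 'greater' or 'two-sided'")

    (s0, f0), (s1, f1) = tab
    n0, n1 = s0 + f0, s1 + f1
    # Fisher one-sided p for every possible table with the same group sizes
    x0 = np.arange(n0 + 1)
    x1 = np.arange(n1 + 1)
    fisher = hypergeom.cdf(x0[:, None], n0 + n1, x0[:, None] + x1[None, :], n0)
    observed = fisher[s0, s1]
    extreme = fisher <= observed + 1e-12
    pi = (np.arange(1, grid_size + 1)) / (grid_size + 1)
    pmf0 = binom.pmf(x0[:, None], n0, pi[None, :])   # (n0+1, G)
    pmf1 = binom.pmf(x1[:, None], n1, pi[None, :])   # (n1+1, G)
    # P(extreme | pi) = sum over extreme (x0, x1) of pmf0[x0] * pmf1[x1]
    probs = np.einsum("ig,jg,ij->g", pmf0, pmf1, extreme.astype(float))
    return float(probs.max())
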