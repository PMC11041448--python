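"""Shared fixtures: small generated cohorts and independent oracle helpers."""

import numpy as np
import pytest

from cevvo.cohort import build_samples
from cevvo.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 patients (8 success / 4 fail) with short runs; fast to preprocess."""
    spec = CohortSpec(n_success=8, n_fail=4, run_length_range=(6.0, 12.0),
                      seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_samples(tiny_cohort):
    """Unscaled samples from the tiny cohort on a 32-step grid (120 total)."""
    return build_samples(tiny_cohort, T=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def binning_oracle(series: np.ndarray, T: int) -> np.ndarray:
    """Naive loop-based reference for length standardization.

    Assign point k to slot floor(k*T/K), average multiply-assigned slots,
    forward-fill gaps, zero before the first filled slot.
    """
    series = np.asarray(series, dtype=float)
    K, V = series.shape
    out = np.zeros((T, V))
    filled = np.zeros(T, dtype=bool)
    for t in range(T):
        pts = [series[k] for k in range(K) if (k * T) // K == t]
        if pts:
            out[t] = np.mean(pts, axis=0)
            filled[t] = True
    last = None
    for t in range(T):
        if filled[t]:
            last = out[t].copy()
        elif last is not None:
            out[t] = last
    return out


def auroc_pairwise_oracle(labels, scores) -> float:
    """Brute force over all positive-negative pairs; ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
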