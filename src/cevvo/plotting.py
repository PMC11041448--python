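"""Matplotlib views of evaluation output: per-day metrics and reliability plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_per_day_metric", "plot_calibration_curve"]


def plot_per_day_metric(table: pd.DataFrame, metric_name: str = "AUROC", ax=None):
    """Per-day metric with CI band and sample-count bars (twin axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ok = table.dropna(subset=["value"])
    ax.plot(ok["day"], ok["value"], color="seagreen", marker="o", label=metric_name)
    ax.fill_between(ok["day"], ok["lower"], ok["upper"], color="seagreen", alpha=0.25)
    ax.set_xlabel("days since cannulation")
    ax.set_ylabel(metric_name)
    ax.set_ylim(0, 1)
    ax2 = ax.twinx()
    ax2.bar(table["day"], table["n"], color="rebeccapurple", alpha=0.3, width=0.8)
    ax2.set_ylabel("samples per day")
    ax.figure.tight_layout()
    return ax


def plot_calibration_curve(curve: pd.DataFrame, ax=None):
    """Reliability diagram with per-bin counts (twin axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = curve.dropna(subset=["mean_score"])
    ax.plot([0, 1], [0, 1], color="seagreen", linestyle="--", label="perfect")
    ax.plot(ok["mean_score"], ok["observed_rate"], marker="o", color="black",
            label="model")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed success rate")
    ax.legend(loc="upper left")
    ax2 = ax.twinx()
    centers = (curve["bin_lower"] + curve["bin_upper"]) / 2
    ax2.bar(centers, curve["count"], width=0.08, color="rebeccapurple", alpha=0.3)
    ax2.set_ylabel("count")
    ax.figure.tight_layout()
    return ax
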