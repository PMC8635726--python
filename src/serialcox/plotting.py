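"""Matplotlib figures for evaluation reports and survival graphs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_risk_distribution", "plot_group_km", "plot_survival_graph"]

_GROUP_COLORS = {"low": "tab:blue", "intermediate": "tab:orange", "high": "tab:red"}


def plot_risk_distribution(report, ax=None):
    """Histogram of predicted risks with tertile cut points."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    ax.hist(report.risks, bins=30, color="lightsteelblue", edgecolor="gray")
    if report.groups is not None:
        for cut in report.groups.cut_points:
            ax.axvline(cut, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("predicted risk (log relative hazard)")
    ax.set_ylabel("patients")
    return ax


def plot_group_km(report, ax=None):
    """Kaplan-Meier curves per risk tertile."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    for label, km in report.group_km.items():
        t, s = km.step_arrays()
        ax.step(t, s, where="post", label=f"{label} (n={report.group_sizes[label]})",
                color=_GROUP_COLORS.get(label))
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    if report.logrank_p is not None:
        ax.set_title(f"log-rank high vs low: p = {report.logrank_p:.2e}", fontsize=9)
    ax.legend(fontsize=8)
    return ax


def plot_survival_graph(result, train_risks=None, axes=None):
    """Risk-distribution marker plus the neighbor KM curve for one patient."""
    if axes is None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0, ax1 = axes
    if train_risks is not None:
        ax0.hist(np.asarray(train_risks), bins=30, color="lightsteelblue",
                 edgecolor="gray")
    ax0.axvline(result.risk, color="tab:red", linewidth=2)
    ax0.set_title(f"risk {result.risk:.3f} (percentile {result.percentile:.1f})",
                  fontsize=9)
    ax0.set_xlabel("predicted risk")
    t, s = result.km.step_arrays()
    ax1.step(t, s, where="post", color="tab:red")
    ax1.set_ylim(0, 1.02)
    ax1.set_xlabel("months")
    ax1.set_ylabel("survival probability")
    ax1.set_title(f"KM of {len(result.neighbor_ids)} risk-nearest patients",
                  fontsize=9)
    return axes
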