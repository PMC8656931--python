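"""Minimal KM and time-dependent ROC figures for pipeline reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .survival import StratifiedCohort  # noqa: E402

GROUP_COLORS = {"low": "#2c7fb8", "intermediate": "#feb24c", "high": "#de2d26"}


def plot_km_groups(strat: StratifiedCohort, path=None, title="Risk groups"):
    """Step plot of the per-group KM curves of a stratified cohort."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in strat.km_curves.items():
        color = GROUP_COLORS.get(str(label))
        ax.step(curve.times, curve.survival, where="post",
                label=f"{label} (n={int((strat.groups == label).sum())})",
                color=color)
        ax.fill_between(curve.times, curve.ci_low, curve.ci_high,
                        step="post", alpha=0.15, color=color)
    ax.set_xlabel("Months")
    ax.set_ylabel("Disease-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_score_distribution(scores, cutoffs=None, path=None):
    """Histogram of risk scores with the stratification cutoffs marked."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(scores, bins=30, color="#888", edgecolor="white")
    for c in (cutoffs or []):
        ax.axvline(c, color="#de2d26", linestyle="--")
    ax.set_xlabel("Risk score")
    ax.set_ylabel("Patients")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
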