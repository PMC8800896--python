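"""ISRF/IRF and paired-IRF panels over rest-score groups."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .item_ordering import paired_irf
from .monotonicity import irf_table
from .response_data import ResponseMatrix

__all__ = ["plot_isrf_panels", "plot_paired_irf"]


def plot_isrf_panels(m: ResponseMatrix, path, minsize: int | None = None):
    """One panel per item: its item step response functions (cumulative
    endorsement probabilities, left axis) and its item response function
    (conditional mean, right axis) across rest-score groups."""
    j = m.n_items
    fig, axes = plt.subplots(1, j, figsize=(3.2 * j, 3.2), squeeze=False)
    for i, ax in enumerate(axes[0]):
        est = irf_table(m, i)
        xs = est.group_midpoints
        for s, k in enumerate(est.steps):
            ax.plot(xs, est.probabilities[:, s], marker="o", ms=3, label=f"P(X≥{k})")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(m.item_labels[i])
        ax.set_xlabel("rest score")
        if i == 0:
            ax.set_ylabel("P(X ≥ k | rest group)")
        ax2 = ax.twinx()
        ax2.plot(xs, est.irf, color="k", ls="--", lw=1.5)
        ax2.set_ylim(m.level_min - 0.1, m.level_max + 0.1)
        if i == j - 1:
            ax2.set_ylabel("E[X | rest group]")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_paired_irf(m: ResponseMatrix, item_a, item_b, path, minsize: int | None = None):
    """Two items' response functions over their shared pair rest score —
    crossing curves indicate an invariant-item-ordering violation."""
    t = paired_irf(m, item_a, item_b, minsize=minsize)
    cols = [c for c in t.columns if c.startswith("irf_")]
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    for c in cols:
        ax.plot(t["group_mid"], t[c], marker="o", ms=4, label=c.removeprefix("irf_"))
    ax.set_xlabel("rest score (other items)")
    ax.set_ylabel("E[X | rest group]")
    ax.set_ylim(m.level_min - 0.1, m.level_max + 0.1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
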