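"""Manifest monotonicity checks for the monotone homogeneity model.

Latent monotonicity implies manifest monotonicity: for every item step k,
``P(X_i >= k | rest score)`` must be non-decreasing in the rest score (the
level sum score minus the item itself).  Persons are binned into contiguous
rest-score groups subject to a minimum group size, the item step response
functions (ISRFs) are estimated per group, and every ordered group pair is
compared: a decrease larger than ``minvi`` (default 0.03) counts as a
violation, each flagged comparison gets a one-sided two-proportion z test,
and an item-level ``crit`` composite summarizes severity (0 when nothing is
flagged).  The item response function (IRF) is the group-conditional mean,
i.e. ``level_min`` plus the sum of the item's ISRFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response_data import ResponseMatrix
from .scalability import compute_h_scale

__all__ = [
    "RestScoreGrouping",
    "IsrfEstimate",
    "ViolationSummary",
    "CRIT_WEIGHTS",
    "default_minsize",
    "make_rest_groups",
    "check_monotonicity",
    "irf_table",
    "crit_value",
]

#: Constants of the documented crit composite (see :func:`crit_value`).
CRIT_WEIGHTS = {
    "h_shortfall": 50.0,   # * max(0, 0.3 - H_i)
    "sqrt_vi": 1.0,        # * sqrt(#vi)
    "vi_fraction": 100.0,  # * #vi / #ac
    "maxvi": 100.0,        # * maxvi
    "sqrt_zmax": 10.0,     # * sqrt(zmax)
}


@dataclass
class RestScoreGrouping:
    """Contiguous rest-score groups, each with at least ``minsize`` persons
    (except when N itself is below ``minsize``: a flagged single group)."""

    lower: np.ndarray        # inclusive lower rest-score bound per group
    upper: np.ndarray        # inclusive upper bound
    counts: np.ndarray
    minsize: int
    degenerate: bool = False  # True when N < minsize forced a single group

    @property
    def n_groups(self) -> int:
        return len(self.counts)

    def assign(self, rest: np.ndarray) -> np.ndarray:
        """Group index for each rest score."""
        return np.searchsorted(self.upper, rest, side="left")

    def midpoints(self, rest: np.ndarray) -> np.ndarray:
        """Mean rest score per group (plotting abscissa)."""
        g = self.assign(rest)
        return np.array([rest[g == k].mean() for k in range(self.n_groups)])

    def labels(self) -> list[str]:
        return [
            f"{lo}" if lo == hi else f"{lo}-{hi}"
            for lo, hi in zip(self.lower, self.upper)
        ]


@dataclass
class IsrfEstimate:
    """Per-group step probabilities and conditional means for one item."""

    item: str
    grouping: RestScoreGrouping
    steps: np.ndarray            # step levels k = level_min+1 .. level_max
    probabilities: np.ndarray    # (n_groups, n_steps): P(X >= k | group)
    irf: np.ndarray              # (n_groups,): E[X | group]
    group_midpoints: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.grouping.labels()
        for g in range(self.grouping.n_groups):
            for s, k in enumerate(self.steps):
                rows.append(
                    {
                        "item": self.item,
                        "group": labels[g],
                        "group_mid": self.group_midpoints[g],
                        "n": int(self.grouping.counts[g]),
                        "step": int(k),
                        "prob_geq": self.probabilities[g, s],
                        "irf": self.irf[g],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ViolationSummary:
    """Violation bookkeeping for one item: active comparisons (#ac), flagged
    violations (#vi), worst violation (maxvi), worst z, and the crit index."""

    item: str
    active_pairs: int
    violations: int
    maxvi: float
    zmax: float
    crit: float
    h_item: float | None = None
    undefined: bool = False
    flagged: list[dict] = field(default_factory=list)


def default_minsize(n: int) -> int:
    """Automatic minimum rest-score-group size: N/10 for N >= 500, else N/5
    with a floor of 50."""
    if n >= 500:
        return n // 10
    return max(n // 5, 50)


def make_rest_groups(rest: np.ndarray, minsize: int) -> RestScoreGrouping:
    """Merge adjacent rest-score values left-to-right until every group has at
    least ``minsize`` persons; an undersized final group is merged into its
    predecessor.  Deterministic."""
    rest = np.asarray(rest)
    values, counts = np.unique(rest, return_counts=True)
    if rest.size < minsize:
        return RestScoreGrouping(
            lower=np.array([values[0]]),
            upper=np.array([values[-1]]),
            counts=np.array([rest.size]),
            minsize=minsize,
            degenerate=True,
        )
    lowers, uppers, sizes = [], [], []
    acc = 0
    start = values[0]
    for v, c in zip(values, counts):
        if start is None:
            start = v
        acc += c
        if acc >= minsize:
            lowers.append(start)
            uppers.append(v)
            sizes.append(acc)
            acc = 0
            start = None
    if acc > 0:  # trailing undersized remainder -> merge into last group
        uppers[-1] = values[-1]
        sizes[-1] += acc
    return RestScoreGrouping(
        lower=np.asarray(lowers),
        upper=np.asarray(uppers),
        counts=np.asarray(sizes),
        minsize=minsize,
    )


def _isrf(m: ResponseMatrix, item: int, grouping: RestScoreGrouping, rest: np.ndarray) -> IsrfEstimate:
    x = m.values[:, item]
    g = grouping.assign(rest)
    steps = np.arange(m.level_min + 1, m.level_max + 1)
    probs = np.empty((grouping.n_groups, len(steps)))
    for gi in range(grouping.n_groups):
        sel = x[g == gi]
        probs[gi] = [(sel >= k).mean() for k in steps]
    irf = m.level_min + probs.sum(axis=1)
    return IsrfEstimate(
        item=m.item_labels[item],
        grouping=grouping,
        steps=steps,
        probabilities=probs,
        irf=irf,
        group_midpoints=grouping.midpoints(rest),
    )


def crit_value(
    h_item: float, violations: int, active: int, maxvi: float, zmax: float
) -> float:
    """Documented weighted composite of misfit severity.

    ``crit = round(50*max(0, 0.3 - H_i) + sqrt(#vi) + 100*#vi/#ac +
    100*maxvi + 10*sqrt(zmax))``; exactly 0 when nothing is flagged.
    Constants live in :data:`CRIT_WEIGHTS`.
    """
    if violations == 0:
        return 0.0
    w = CRIT_WEIGHTS
    hi = h_item if np.isfinite(h_item) else 0.0
    return float(
        round(
            w["h_shortfall"] * max(0.0, 0.3 - hi)
            + w["sqrt_vi"] * np.sqrt(violations)
            + w["vi_fraction"] * violations / max(active, 1)
            + w["maxvi"] * maxvi
            + w["sqrt_zmax"] * np.sqrt(max(zmax, 0.0))
        )
    )


def check_monotonicity(
    m: ResponseMatrix,
    item: int | str,
    minvi: float = 0.03,
    minsize: int | None = None,
) -> tuple[IsrfEstimate, ViolationSummary]:
    """Check one item's manifest monotonicity over rest-score groups.

    For every step k and ordered group pair g < g', flag a violation when
    ``P_g(X >= k) - P_g'(X >= k) > minvi``; attach a one-sided two-proportion
    z test to each flagged comparison.  All (step, group-pair) comparisons
    count as active.
    """
    i = m.item_index(item)
    label = m.item_labels[i]
    if minsize is None:
        minsize = default_minsize(m.n_persons)
    x = m.values[:, i]
    if x.min() == x.max():
        grouping = make_rest_groups(m.rest_scores([i]), minsize)
        est = _isrf(m, i, grouping, m.rest_scores([i]))
        return est, ViolationSummary(
            item=label, active_pairs=0, violations=0, maxvi=0.0, zmax=0.0,
            crit=0.0, h_item=float("nan"), undefined=True,
        )
    rest = m.rest_scores([i])
    grouping = make_rest_groups(rest, minsize)
    est = _isrf(m, i, grouping, rest)
    h_item = compute_h_scale(m).h_item[i] if m.n_items >= 2 else float("nan")
    probs = est.probabilities
    ns = grouping.counts
    ac = 0
    vi = 0
    maxvi = 0.0
    zmax = 0.0
    flagged = []
    ngr = grouping.n_groups
    for s in range(probs.shape[1]):
        for g1 in range(ngr):
            for g2 in range(g1 + 1, ngr):
                ac += 1
                diff = probs[g1, s] - probs[g2, s]
                if diff > minvi:
                    vi += 1
                    maxvi = max(maxvi, diff)
                    n1, n2 = ns[g1], ns[g2]
                    pooled = (probs[g1, s] * n1 + probs[g2, s] * n2) / (n1 + n2)
                    se = np.sqrt(max(pooled * (1 - pooled), 1e-12) * (1 / n1 + 1 / n2))
                    z = diff / se
                    zmax = max(zmax, z)
                    flagged.append(
                        {
                            "step": int(est.steps[s]),
                            "group_lo": grouping.labels()[g1],
                            "group_hi": grouping.labels()[g2],
                            "diff": float(diff),
                            "z": float(z),
                        }
                    )
    summary = ViolationSummary(
        item=label,
        active_pairs=ac,
        violations=vi,
        maxvi=maxvi,
        zmax=zmax,
        crit=crit_value(h_item, vi, ac, maxvi, zmax),
        h_item=float(h_item),
        flagged=flagged,
    )
    return est, summary


def irf_table(
    m: ResponseMatrix, item: int | str, grouping: RestScoreGrouping | None = None
) -> IsrfEstimate:
    """Plotting-ready ISRF/IRF estimate for one item (shared grouping optional)."""
    i = m.item_index(item)
    rest = m.rest_scores([i])
    if grouping is None:
        grouping = make_rest_groups(rest, default_minsize(m.n_persons))
    return _isrf(m, i, grouping, rest)
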