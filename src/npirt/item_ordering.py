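"""Manifest invariant item ordering (MIIO) and the H^T coefficient.

The double monotonicity model adds nonintersecting response functions to the
monotone homogeneity model, which licenses one fixed item ordering along the
latent trait.  MIIO checks this manifestly: items are ordered by their mean
scores (higher mean = easier to endorse, i.e. more problems reported — the
convention used throughout, so reports list the easiest item first), and for
each ordered pair the conditional means are compared across groups of the
rest score computed from the *other* J-2 items.  A reversal larger than
``minvi_pair`` — default ``(#ISRFs) * 0.03 = (level_max - level_min) * 0.03``,
i.e. 0.12 for five-level items — is flagged and tested with a one-sided
paired t test.  Backward selection removes the worst item until no flagged
reversal remains.

Coefficient H^T is the scale scalability coefficient computed on the
transposed matrix (persons as items), after dropping persons with constant
response patterns; it quantifies how accurately the sample follows the item
ordering (< 0.3 too low, 0.3-0.4 low, 0.4-0.5 moderate, > 0.5 high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .monotonicity import crit_value, default_minsize, make_rest_groups
from .response_data import ConfigError, ResponseMatrix
from .scalability import compute_h_scale

__all__ = [
    "PairCheck",
    "IIOReport",
    "check_miio",
    "backward_selection",
    "coefficient_ht",
    "classify_ht",
    "paired_irf",
]


@dataclass
class PairCheck:
    """MIIO bookkeeping for one ordered item pair (easy first)."""

    easy: str
    hard: str
    active_pairs: int
    violations: int
    significant_violations: int
    maxvi: float
    tmax: float
    flagged: list[dict] = field(default_factory=list)


@dataclass
class IIOReport:
    """Result of a MIIO check (optionally after backward selection)."""

    item_order: list[str]            # easiest (highest mean) first
    item_means: dict[str, float]
    pairs: list[PairCheck]
    item_summary: pd.DataFrame       # per item: ac, vi, sig_vi, maxvi, tmax, crit
    removed_items: list[str] = field(default_factory=list)
    ht: float = float("nan")
    tied_means: list[tuple[str, str]] = field(default_factory=list)
    minvi_pair: float = float("nan")

    @property
    def total_violations(self) -> int:
        return sum(p.violations for p in self.pairs)


def _miio_minvi(m: ResponseMatrix) -> float:
    return (m.level_max - m.level_min) * 0.03


def check_miio(
    m: ResponseMatrix,
    minvi_pair: float | None = None,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> IIOReport:
    """Check every ordered item pair for manifest invariant item ordering.

    Requires J >= 3: with two items the pair's rest score would be computed
    from zero items.
    """
    if m.n_items < 3:
        raise ConfigError(
            "MIIO needs at least 3 items: the pair rest score is computed from "
            "the other J-2 items"
        )
    if minvi_pair is None:
        minvi_pair = _miio_minvi(m)
    if minsize is None:
        minsize = default_minsize(m.n_persons)
    means = m.values.mean(axis=0)
    # easiest (largest mean) first; ties broken by item index and flagged,
    # because invariant ordering is ill-defined under ties
    order = sorted(range(m.n_items), key=lambda i: (-means[i], i))
    tied = [
        (m.item_labels[order[k]], m.item_labels[order[k + 1]])
        for k in range(len(order) - 1)
        if means[order[k]] == means[order[k + 1]]
    ]
    scal = compute_h_scale(m)
    pairs: list[PairCheck] = []
    per_item: dict[str, dict] = {
        lab: {"ac": 0, "vi": 0, "sig_vi": 0, "maxvi": 0.0, "tmax": 0.0}
        for lab in m.item_labels
    }
    for a_pos in range(len(order)):
        for b_pos in range(a_pos + 1, len(order)):
            ie, ih = order[a_pos], order[b_pos]  # easy, hard
            rest = m.rest_scores([ie, ih])
            grouping = make_rest_groups(rest, minsize)
            g = grouping.assign(rest)
            ac = grouping.n_groups
            vi = sig = 0
            maxvi = tmax = 0.0
            flagged = []
            for gi in range(grouping.n_groups):
                sel = g == gi
                xe = m.values[sel, ie].astype(float)
                xh = m.values[sel, ih].astype(float)
                diff = xh.mean() - xe.mean()
                if diff > minvi_pair:
                    vi += 1
                    maxvi = max(maxvi, diff)
                    d = xh - xe
                    sd = d.std(ddof=1)
                    n_g = len(d)
                    t = diff / (sd / np.sqrt(n_g)) if sd > 0 and n_g > 1 else np.inf
                    tmax = max(tmax, t)
                    significant = (
                        n_g > 1
                        and t > stats.t.ppf(1 - alpha, df=n_g - 1)
                    )
                    sig += int(significant)
                    flagged.append(
                        {
                            "group": grouping.labels()[gi],
                            "diff": float(diff),
                            "t": float(t),
                            "significant": bool(significant),
                        }
                    )
            pairs.append(
                PairCheck(
                    easy=m.item_labels[ie],
                    hard=m.item_labels[ih],
                    active_pairs=ac,
                    violations=vi,
                    significant_violations=sig,
                    maxvi=maxvi,
                    tmax=tmax,
                    flagged=flagged,
                )
            )
            for lab in (m.item_labels[ie], m.item_labels[ih]):
                agg = per_item[lab]
                agg["ac"] += ac
                agg["vi"] += vi
                agg["sig_vi"] += sig
                agg["maxvi"] = max(agg["maxvi"], maxvi)
                agg["tmax"] = max(agg["tmax"], tmax)
    rows = []
    for idx, lab in enumerate(m.item_labels):
        agg = per_item[lab]
        hi = float(scal.h_item[idx])
        rows.append(
            {
                "item": lab,
                "mean": float(means[idx]),
                "h_item": hi,
                "ac": agg["ac"],
                "vi": agg["vi"],
                "sig_vi": agg["sig_vi"],
                "maxvi": agg["maxvi"],
                "tmax": agg["tmax"],
                "crit": crit_value(hi, agg["vi"], agg["ac"], agg["maxvi"], agg["tmax"]),
            }
        )
    return IIOReport(
        item_order=[m.item_labels[i] for i in order],
        item_means={m.item_labels[i]: float(means[i]) for i in range(m.n_items)},
        pairs=pairs,
        item_summary=pd.DataFrame(rows),
        ht=coefficient_ht(m),
        tied_means=tied,
        minvi_pair=float(minvi_pair),
    )


def backward_selection(
    m: ResponseMatrix,
    report: IIOReport | None = None,
    minvi_pair: float | None = None,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> IIOReport:
    """Iteratively remove the worst-violating item until no flagged reversal
    remains.

    Removal rule (documented, configurable only through the code): the item
    with the most *significant* violations; ties broken by larger crit, then
    by lower item index.  Stops at J = 3 with the remaining violations left
    in the report.
    """
    current = m
    rep = report if report is not None else check_miio(current, minvi_pair, minsize, alpha)
    removed: list[str] = []
    while rep.total_violations > 0 and current.n_items > 3:
        s = rep.item_summary
        order = {lab: k for k, lab in enumerate(current.item_labels)}
        worst = s.sort_values(
            by=["sig_vi", "crit", "item"],
            ascending=[False, False, True],
            key=lambda col: col.map(order) if col.name == "item" else col,
        ).iloc[0]["item"]
        removed.append(str(worst))
        current = current.drop_items([worst])
        rep = check_miio(current, minvi_pair, minsize, alpha)
    rep.removed_items = removed
    return rep


def coefficient_ht(m: ResponseMatrix) -> float:
    """H^T: scale scalability of the transposed matrix (persons as items).

    Persons with zero response variance are removed first (their H with any
    other person is undefined); NaN when fewer than two non-constant persons
    remain.  Computed via sums over sorted rows, so it is O(N log J) rather
    than O(N^2), and identical to ``compute_h_scale`` on the transposed
    matrix.
    """
    x = m.values.astype(float)
    keep = x.std(axis=1) > 0
    x = x[keep]
    n, j = x.shape
    if n < 2:
        return float("nan")
    row_mean = x.mean(axis=1)
    row_var = x.var(axis=1)
    col_sum_sq = (x.sum(axis=0) ** 2).sum()
    s2 = row_mean.sum() ** 2
    sum_cov_all = col_sum_sq / j - s2              # sum over all (p, q) incl. p = q
    srt = np.sort(x, axis=1)
    sum_covmax_all = (srt.sum(axis=0) ** 2).sum() / j - s2
    num = (sum_cov_all - row_var.sum()) / 2.0
    den = (sum_covmax_all - row_var.sum()) / 2.0
    if den <= 0:
        return float("nan")
    return float(num / den)


def classify_ht(ht: float) -> str:
    """Accuracy label for the item ordering implied by H^T."""
    if not np.isfinite(ht):
        return "undefined"
    if ht < 0.3:
        return "too low"
    if ht < 0.4:
        return "low"
    if ht <= 0.5:
        return "moderate"
    return "high"


def paired_irf(
    m: ResponseMatrix,
    item_a: int | str,
    item_b: int | str,
    minsize: int | None = None,
) -> pd.DataFrame:
    """Conditional means of two items over shared groups of their joint rest
    score (the other J-2 items) — the plotting surface for paired IRFs."""
    if m.n_items < 3:
        raise ConfigError("paired IRFs need at least 3 items")
    ia, ib = m.item_index(item_a), m.item_index(item_b)
    if ia == ib:
        raise ConfigError("need two distinct items")
    if minsize is None:
        minsize = default_minsize(m.n_persons)
    rest = m.rest_scores([ia, ib])
    grouping = make_rest_groups(rest, minsize)
    g = grouping.assign(rest)
    rows = []
    labels = grouping.labels()
    for gi in range(grouping.n_groups):
        sel = g == gi
        rows.append(
            {
                "group": labels[gi],
                "group_mid": rest[sel].mean(),
                "n": int(sel.sum()),
                f"irf_{m.item_labels[ia]}": m.values[sel, ia].mean(),
                f"irf_{m.item_labels[ib]}": m.values[sel, ib].mean(),
            }
        )
    return pd.DataFrame(rows)
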