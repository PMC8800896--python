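"""Total-score reliability: Guttman's lambda-2 and the Molenaar-Sijtsma rho.

Both are estimates of the reliability of the level sum score.  Lambda-2 is
the classical covariance-based lower bound

    lambda2 = [S_T - sum_j s_j^2 + sqrt( J/(J-1) * sum_{i != j} s_ij^2 )] / S_T

with S_T the total-score variance; it always dominates Cronbach's alpha.

The Molenaar-Sijtsma statistic works on item *steps* (the binary indicators
``X_i >= k``).  Between-item step covariances estimate true-score covariances
directly under local independence; the within-item terms — which would need
independent replications — are approximated by ordering all steps by
popularity and interpolating each within-item joint probability from the
observed joints of neighbouring steps that belong to *other* items (linear in
the marginal, ratio extrapolation at the edges; the 1988 construction).  The
approximated Frechet-feasible joints are plugged into the total-score
variance decomposition:

    rho = [sum_between sigma_gh + sum_within (pi~_gh - pi_g pi_h)] / Var(X+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .response_data import ConfigError, ResponseMatrix

__all__ = [
    "ReliabilityReport",
    "guttman_lambda2",
    "cronbach_alpha",
    "ms_rho",
    "reliability_report",
]


@dataclass
class ReliabilityReport:
    lambda2: float          # raw value
    lambda2_clipped: float  # clipped to [0, 1]
    ms_rho: float
    ms_rho_clipped: float
    alpha: float            # Cronbach's alpha, internal cross-check
    undefined: bool = False
    note: str = ""


def _covariance(m: ResponseMatrix) -> np.ndarray:
    return np.cov(m.values.T, ddof=1)


def guttman_lambda2(m: ResponseMatrix) -> float:
    """Guttman's lambda-2 (invariant to the covariance ddof choice)."""
    s = _covariance(m)
    j = m.n_items
    st = s.sum()
    if st <= 0:
        return float("nan")
    off = s[~np.eye(j, dtype=bool)]
    return float((st - np.trace(s) + np.sqrt(j / (j - 1) * (off**2).sum())) / st)


def cronbach_alpha(m: ResponseMatrix) -> float:
    s = _covariance(m)
    st = s.sum()
    if st <= 0:
        return float("nan")
    j = m.n_items
    return float(j / (j - 1) * (1 - np.trace(s) / st))


def _step_indicators(m: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary N x K matrix of item steps and the item index of each step."""
    cols, owner = [], []
    for i in range(m.n_items):
        for k in range(m.level_min + 1, m.level_max + 1):
            cols.append((m.values[:, i] >= k).astype(float))
            owner.append(i)
    return np.column_stack(cols), np.asarray(owner)


def _interpolate_within(
    pi: np.ndarray, joint: np.ndarray, owner: np.ndarray
) -> np.ndarray:
    """Approximate within-item joint step probabilities.

    Steps are sorted by popularity (descending).  For a within-item pair
    (g, h): find g's nearest neighbours in the sorted order that belong to a
    different item, and interpolate the column ``joint[., h]`` linearly in the
    marginal pi between them; at the edges use ratio (toward 0) or
    complement-ratio (toward 1) extrapolation.  Results are symmetrized and
    clamped into the Frechet bounds (diagonal: [pi^2, pi])."""
    k = len(pi)
    order = np.argsort(-pi, kind="stable")
    pos = np.empty(k, dtype=int)
    pos[order] = np.arange(k)
    est = joint.copy()

    def neighbour(g: int, direction: int) -> int | None:
        p = pos[g] + direction
        while 0 <= p < k:
            cand = order[p]
            if owner[cand] != owner[g]:
                return cand
            p += direction
        return None

    for g in range(k):
        for h in range(k):
            if owner[g] != owner[h]:
                continue
            prev = neighbour(g, -1)  # more popular
            nxt = neighbour(g, +1)   # less popular
            if prev is not None and nxt is not None:
                denom = pi[prev] - pi[nxt]
                w = (pi[g] - pi[nxt]) / denom if denom > 0 else 0.5
                val = w * joint[prev, h] + (1 - w) * joint[nxt, h]
            elif prev is not None:
                val = joint[prev, h] * (pi[g] / pi[prev]) if pi[prev] > 0 else 0.0
            elif nxt is not None:
                # extrapolate toward certainty along the complement
                comp = 1 - pi[nxt]
                val = (
                    pi[h] - (pi[h] - joint[nxt, h]) * (1 - pi[g]) / comp
                    if comp > 0
                    else min(pi[g], pi[h])
                )
            else:  # pragma: no cover - impossible for J >= 2
                val = pi[g] * pi[h]
            est[g, h] = val
    est = (est + est.T) / 2.0
    for g in range(k):
        for h in range(k):
            if owner[g] != owner[h]:
                continue
            lo = max(0.0, pi[g] + pi[h] - 1.0)
            hi = min(pi[g], pi[h])
            if g == h:
                lo = max(lo, pi[g] ** 2)
            est[g, h] = min(max(est[g, h], lo), hi)
    return est


def ms_rho(m: ResponseMatrix) -> float:
    """Molenaar-Sijtsma reliability of the level sum score (J >= 3)."""
    if m.n_items < 3:
        raise ConfigError(
            "the Molenaar-Sijtsma statistic needs J >= 3 items so every step "
            "has interpolation neighbours from other items"
        )
    y, owner = _step_indicators(m)
    n = y.shape[0]
    pi = y.mean(axis=0)
    joint = y.T @ y / n
    var_total = float(y.sum(axis=1).var())  # population variance of X+
    if var_total <= 0:
        return float("nan")
    sigma_obs = joint - np.outer(pi, pi)
    est = _interpolate_within(pi, joint, owner)
    sigma_true = est - np.outer(pi, pi)
    same_item = owner[:, None] == owner[None, :]
    numerator = sigma_obs[~same_item].sum() + sigma_true[same_item].sum()
    return float(numerator / var_total)


def reliability_report(m: ResponseMatrix) -> ReliabilityReport:
    """Lambda-2, MS-rho and alpha in one report; undefined-flagged when the
    total score has zero variance."""
    lam = guttman_lambda2(m)
    alpha = cronbach_alpha(m)
    try:
        rho = ms_rho(m)
    except ConfigError:
        rho = float("nan")
    undefined = not np.isfinite(lam)
    note = "total-score variance is zero" if undefined else ""
    clip = lambda v: float(min(max(v, 0.0), 1.0)) if np.isfinite(v) else float("nan")
    return ReliabilityReport(
        lambda2=float(lam),
        lambda2_clipped=clip(lam),
        ms_rho=float(rho),
        ms_rho_clipped=clip(rho),
        alpha=float(alpha),
        undefined=undefined,
        note=note,
    )
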