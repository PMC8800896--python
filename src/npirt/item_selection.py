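"""Automated item selection procedure (AISP) and the lower-bound sweep.

The hierarchical AISP greedily partitions items into Mokken scales at a lower
bound ``c`` on scalability:

1. seed a new scale with the pair maximizing H_ij among pairs whose H_ij is
   at least ``c`` and significantly positive;
2. repeatedly add the unselected item that maximizes the scale's H, subject
   to (a) its H with the current selection being at least ``c`` and (b)
   significantly positive covariances with every selected item;
3. repeat on the leftovers to form further scales; items never seeded are
   unscalable (scale id 0).

Significance uses the normal-theory z test of Cov > 0 (``z = r * sqrt(N-1)``)
with a Bonferroni correction over all J(J-1)/2 item pairs.  Ties on H break
toward the lowest item index, making the procedure fully deterministic.

The lower-bound sweep re-runs the AISP over a grid of ``c`` values (default
0.00 .. 0.55 in steps of 0.05, twelve runs) and a per-item refinement then
pinpoints, to a stated resolution (default 0.001), the smallest ``c`` at
which an item leaves the scale — the item's exclusion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .response_data import ResponseMatrix
from .scalability import ScalabilityResult, compute_h_scale

__all__ = [
    "AispConfig",
    "AispResult",
    "run_aisp",
    "sweep_lbound",
    "refine_exclusion_threshold",
    "membership_table",
]


@dataclass
class AispConfig:
    """AISP settings: lower bound c (default 0.3), test level alpha, and the
    multiple-comparison rule (``"bonferroni"`` or ``"none"``)."""

    lbound: float = 0.3
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lbound < 1.0):
            raise ValueError("lower bound c must lie in [0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class AispResult:
    """Scale assignment (0 = unscalable) plus per-scale item sets and H_s."""

    item_labels: list[str]
    scale_assignment: np.ndarray           # J ints, 0 = unscalable
    scale_h: dict[int, float] = field(default_factory=dict)
    lbound: float = 0.3

    def scales(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, s in zip(self.item_labels, self.scale_assignment):
            if s > 0:
                out.setdefault(int(s), []).append(lab)
        return out

    def selected(self, item: int | str) -> bool:
        if isinstance(item, str):
            item = self.item_labels.index(item)
        return self.scale_assignment[item] > 0


def _z_threshold(cfg: AispConfig, n_items: int) -> float:
    n_pairs = n_items * (n_items - 1) // 2
    alpha = cfg.alpha / n_pairs if cfg.correction == "bonferroni" else cfg.alpha
    return float(stats.norm.ppf(1 - alpha))


def _scale_h(cov: np.ndarray, covmax: np.ndarray, items: list[int]) -> float:
    idx = np.asarray(items)
    num = den = 0.0
    for p in range(len(idx)):
        for q in range(p + 1, len(idx)):
            num += cov[idx[p], idx[q]]
            den += covmax[idx[p], idx[q]]
    return num / den if den > 0 else float("nan")


def _item_h_with(cov: np.ndarray, covmax: np.ndarray, item: int, sel: list[int]) -> float:
    num = sum(cov[item, s] for s in sel)
    den = sum(covmax[item, s] for s in sel)
    return num / den if den > 0 else float("nan")


def run_aisp(m: ResponseMatrix, cfg: AispConfig | None = None) -> AispResult:
    """Partition the items into Mokken scales at lower bound ``cfg.lbound``.

    Deterministic: ties on H break toward lower item indices.  An
    all-unscalable result is valid (e.g. at a bound above every sample H).
    """
    cfg = cfg or AispConfig()
    base: ScalabilityResult = compute_h_scale(m)
    # reconstruct cov/covmax from H and z is lossy; recompute directly
    from .scalability import _cov_and_covmax  # shared internal

    cov, covmax = _cov_and_covmax(m)
    j = m.n_items
    zcrit = _z_threshold(cfg, j)
    h_pair, z_pair = base.h_pair, base.z_pair
    assignment = np.zeros(j, dtype=int)
    remaining = [i for i in range(j) if i not in base.undefined_items]
    scale_id = 0
    scale_h: dict[int, float] = {}
    while len(remaining) >= 2:
        # --- seed: best significantly-positive pair with H_ij >= c ---------
        best_pair, best_h = None, -np.inf
        for ai in range(len(remaining)):
            for bi in range(ai + 1, len(remaining)):
                a, b = remaining[ai], remaining[bi]
                hij, zij = h_pair[a, b], z_pair[a, b]
                if not np.isfinite(hij) or hij < cfg.lbound or hij <= 0:
                    continue
                if zij < zcrit:
                    continue
                if hij > best_h:
                    best_h, best_pair = hij, (a, b)
        if best_pair is None:
            break
        scale_id += 1
        sel = list(best_pair)
        pool = [i for i in remaining if i not in sel]
        # --- grow ----------------------------------------------------------
        while True:
            best_item, best_scale_h = None, -np.inf
            for cand in pool:
                if any(z_pair[cand, s] < zcrit or cov[cand, s] <= 0 for s in sel):
                    continue
                if _item_h_with(cov, covmax, cand, sel) < cfg.lbound:
                    continue
                h_new = _scale_h(cov, covmax, sel + [cand])
                if h_new > best_scale_h:
                    best_scale_h, best_item = h_new, cand
            if best_item is None:
                break
            sel.append(best_item)
            pool.remove(best_item)
        for s in sel:
            assignment[s] = scale_id
        scale_h[scale_id] = _scale_h(cov, covmax, sorted(sel))
        remaining = [i for i in remaining if i not in sel]
    return AispResult(
        item_labels=list(m.item_labels),
        scale_assignment=assignment,
        scale_h=scale_h,
        lbound=cfg.lbound,
    )


def sweep_lbound(
    m: ResponseMatrix,
    grid_start: float = 0.0,
    grid_stop: float = 0.55,
    grid_step: float = 0.05,
    cfg: AispConfig | None = None,
) -> dict[float, AispResult]:
    """Run the AISP once per grid value of the lower bound c."""
    if not (0.0 <= grid_start < grid_stop) or grid_step <= 0:
        raise ValueError("need 0 <= start < stop and step > 0")
    n = int(round((grid_stop - grid_start) / grid_step)) + 1
    grid = np.round(grid_start + grid_step * np.arange(n), 10)
    grid = grid[grid <= grid_stop + 1e-12]
    if len(grid) == 0:
        raise ValueError("empty lower-bound grid")
    base = cfg or AispConfig()
    out: dict[float, AispResult] = {}
    for c in grid:
        out[float(c)] = run_aisp(m, AispConfig(float(c), base.alpha, base.correction))
    return out


def membership_table(sweep: dict[float, AispResult]) -> pd.DataFrame:
    """Items x lower-bound table of scale ids (0 = unscalable)."""
    cs = sorted(sweep)
    labels = sweep[cs[0]].item_labels
    data = {f"c={c:.2f}": sweep[c].scale_assignment for c in cs}
    return pd.DataFrame(data, index=labels)


def refine_exclusion_threshold(
    m: ResponseMatrix,
    item: int | str,
    resolution: float = 0.001,
    cfg: AispConfig | None = None,
) -> float | None:
    """Smallest lower bound c (to ``resolution``) at which ``item`` is no
    longer selected into any scale; ``None`` ("never") if the item survives
    every c in [0, 1).

    Selection is monotone non-increasing in c, so the threshold is located by
    bisection on the grid of multiples of ``resolution``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    base = cfg or AispConfig()
    idx = m.item_index(item)

    def selected_at(c: float) -> bool:
        return run_aisp(m, AispConfig(c, base.alpha, base.correction)).selected(idx)

    hi = int(np.ceil(1.0 / resolution)) - 1  # largest grid point < 1
    if selected_at(hi * resolution):
        return None
    lo = 0
    if not selected_at(0.0):
        return 0.0
    # invariant: selected at lo*res, not selected at hi*res
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if selected_at(mid * resolution):
            lo = mid
        else:
            hi = mid
    return float(np.round(hi * resolution, 10))
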