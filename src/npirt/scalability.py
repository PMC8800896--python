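"""Loevinger scalability coefficients for polytomous Mokken scale analysis.

H_ij is the covariance of an item pair normed by the maximum covariance
attainable given the two items' marginal level distributions (the covariance
of the comonotonic, Frechet-upper-bound coupling).  H_i norms the sum of an
item's covariances with the other items by the sum of the corresponding
maxima (algebraically the normed item-rest covariance), and H_s does the same
over all pairs, making it a weighted mean of the H_i.

Conventions (documented once, used everywhere):

* covariances use the population 1/N denominator in numerator and normalizer
  alike; every H ratio is invariant to this choice as long as both match;
* positivity tests are normal-theory z statistics ``z_ij = r_ij * sqrt(N-1)``
  for Cov > 0;
* zero-variance items yield NaN H values plus an explicit ``undefined_items``
  flag list — they are never silently dropped.

H_ij > 0 for all pairs is a necessary condition of the monotone homogeneity
model; negative values are reported as model violations.  Rules of thumb:
H_s < 0.3 unscalable, 0.3-0.4 weak, 0.4-0.5 moderate, >= 0.5 strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .response_data import ResponseMatrix, ValidationError

__all__ = [
    "ScalabilityResult",
    "max_covariance",
    "compute_h_pair",
    "compute_h_item",
    "compute_h_scale",
    "standard_errors",
    "classify_scale",
    "scale_strength_labels",
]

scale_strength_labels = {
    "unscalable": "H_s < 0.3",
    "weak": "0.3 <= H_s < 0.4",
    "moderate": "0.4 <= H_s < 0.5",
    "strong": "H_s >= 0.5",
}


@dataclass
class ScalabilityResult:
    """H coefficients at pair, item and scale level, with optional SEs."""

    item_labels: list[str]
    h_pair: np.ndarray            # J x J, NaN diagonal
    h_item: np.ndarray            # J
    h_scale: float
    z_pair: np.ndarray            # positivity-test z statistics, J x J
    n_persons: int
    undefined_items: list[int] = field(default_factory=list)
    se_pair: np.ndarray | None = None
    se_item: np.ndarray | None = None
    se_scale: float | None = None
    bootstrap_b: int | None = None
    seed: int | None = None

    @property
    def label(self) -> str:
        return classify_scale(self.h_scale)

    def negative_pairs(self) -> list[tuple[str, str, float]]:
        """Item pairs with negative H_ij — monotone-homogeneity violations."""
        out = []
        j = len(self.item_labels)
        for a in range(j):
            for b in range(a + 1, j):
                if np.isfinite(self.h_pair[a, b]) and self.h_pair[a, b] < 0:
                    out.append(
                        (self.item_labels[a], self.item_labels[b], float(self.h_pair[a, b]))
                    )
        return out


def _marginal_counts(x: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return np.bincount(
        np.searchsorted(levels, x), minlength=len(levels)
    )


def max_covariance(
    marginal_i: np.ndarray,
    marginal_j: np.ndarray,
    levels_i: np.ndarray | None = None,
    levels_j: np.ndarray | None = None,
) -> float:
    """Maximum covariance attainable by any coupling of two level marginals.

    The maximizing coupling is the comonotonic one: pair the sorted samples
    (equivalently, the northwest-corner pairing of the two cumulative
    frequency ladders).  Marginals are level-frequency count vectors with
    equal totals N; ``levels_*`` give the level values (default
    ``1..len(marginal)``).  Population (1/N) covariance.
    """
    fi = np.asarray(marginal_i, dtype=float)
    fj = np.asarray(marginal_j, dtype=float)
    if fi.sum() != fj.sum():
        raise ValidationError(
            f"marginal totals differ: {fi.sum()} vs {fj.sum()}"
        )
    n = fi.sum()
    if n <= 0:
        raise ValidationError("empty marginals")
    li = np.arange(1, len(fi) + 1, dtype=float) if levels_i is None else np.asarray(levels_i, float)
    lj = np.arange(1, len(fj) + 1, dtype=float) if levels_j is None else np.asarray(levels_j, float)
    ci = np.cumsum(fi)
    cj = np.cumsum(fj)
    # walk the merged cumulative breakpoints: each segment of probability mass
    # is matched between the level it occupies in each ladder
    bounds = np.union1d(ci, cj)
    prev = 0.0
    exy = 0.0
    for b in bounds:
        mass = b - prev
        if mass <= 0:
            continue
        ii = int(np.searchsorted(ci, prev, side="right"))
        jj = int(np.searchsorted(cj, prev, side="right"))
        exy += mass * li[ii] * lj[jj]
        prev = b
    ex = float(fi @ li) / n
    ey = float(fj @ lj) / n
    return exy / n - ex * ey


def _cov_and_covmax(m: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Observed (population) covariance matrix and pairwise covariance maxima."""
    x = m.values
    j = m.n_items
    cov = np.cov(x.T, bias=True)
    levels = np.arange(m.level_min, m.level_max + 1)
    counts = np.stack([
        np.bincount(x[:, i] - m.level_min, minlength=m.n_levels) for i in range(j)
    ])
    covmax = np.zeros((j, j))
    for a in range(j):
        covmax[a, a] = cov[a, a]
        for b in range(a + 1, j):
            covmax[a, b] = covmax[b, a] = max_covariance(
                counts[a], counts[b], levels, levels
            )
    return cov, covmax


def _assemble(m: ResponseMatrix) -> ScalabilityResult:
    cov, covmax = _cov_and_covmax(m)
    j = m.n_items
    n = m.n_persons
    variances = np.diag(cov)
    undefined = [i for i in range(j) if variances[i] <= 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pair = np.where(covmax > 0, cov / covmax, np.nan)
    np.fill_diagonal(h_pair, np.nan)
    off = ~np.eye(j, dtype=bool)
    num_item = np.where(off, cov, 0.0).sum(axis=1)
    den_item = np.where(off, covmax, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_item = np.where(den_item > 0, num_item / den_item, np.nan)
    den_scale = np.where(off, covmax, 0.0).sum() / 2.0
    h_scale = float(np.where(off, cov, 0.0).sum() / 2.0 / den_scale) if den_scale > 0 else float("nan")
    # positivity test of Cov_ij > 0: correlation-based normal-theory z
    sd = np.sqrt(np.maximum(variances, 0.0))
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / denom, np.nan)
    z_pair = r * np.sqrt(max(n - 1, 1))
    np.fill_diagonal(z_pair, np.nan)
    return ScalabilityResult(
        item_labels=list(m.item_labels),
        h_pair=h_pair,
        h_item=h_item,
        h_scale=h_scale,
        z_pair=z_pair,
        n_persons=n,
        undefined_items=undefined,
    )


def compute_h_pair(m: ResponseMatrix, i: int | str, j: int | str) -> float:
    """H_ij = Cov(X_i, X_j) / Covmax(X_i, X_j); 1 iff the joint is comonotonic."""
    a, b = m.item_index(i), m.item_index(j)
    return float(_assemble(m).h_pair[a, b])


def compute_h_item(m: ResponseMatrix, i: int | str) -> float:
    """H_i: the item's summed covariance with the rest, normed by the summed maxima."""
    return float(_assemble(m).h_item[m.item_index(i)])


def compute_h_scale(m: ResponseMatrix) -> ScalabilityResult:
    """Full scalability surface: H_ij matrix, H_i vector, H_s, positivity z's."""
    return _assemble(m)


def standard_errors(
    m: ResponseMatrix,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int | None = None,
) -> ScalabilityResult:
    """Fill bootstrap standard errors into a :class:`ScalabilityResult`.

    Nonparametric person-resampling bootstrap, seeded and reproducible.
    """
    if method != "bootstrap":
        raise ValueError(f"unknown SE method {method!r}; only 'bootstrap' is implemented")
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    res = _assemble(m)
    rng = np.random.default_rng(seed)
    j = m.n_items
    hp = np.empty((B, j, j))
    hi = np.empty((B, j))
    hs = np.empty(B)
    n = m.n_persons
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        rep = ResponseMatrix(
            m.values[idx], m.level_min, m.level_max, list(m.item_labels)
        )
        r = _assemble(rep)
        hp[b] = r.h_pair
        hi[b] = r.h_item
        hs[b] = r.h_scale
    import warnings

    with warnings.catch_warnings():
        # the h_pair diagonal is all-NaN by construction
        warnings.simplefilter("ignore", RuntimeWarning)
        res.se_pair = np.nanstd(hp, axis=0, ddof=1)
        res.se_item = np.nanstd(hi, axis=0, ddof=1)
        res.se_scale = float(np.nanstd(hs, ddof=1)) if np.isfinite(hs).any() else float("nan")
    np.fill_diagonal(res.se_pair, np.nan)
    if res.undefined_items:
        # a constant item has no sampling variability in its (undefined) H
        res.se_item[res.undefined_items] = 0.0
    res.bootstrap_b = B
    res.seed = seed
    return res


def to_long_frame(res: ScalabilityResult):
    """Long-format table of H estimates (one row per pair, item and the
    scale, with SE and positivity z where available)."""
    import pandas as pd

    rows = []
    j = len(res.item_labels)
    for a in range(j):
        for b in range(a + 1, j):
            rows.append(
                {
                    "level": "pair",
                    "unit": f"{res.item_labels[a]}:{res.item_labels[b]}",
                    "estimate": res.h_pair[a, b],
                    "se": res.se_pair[a, b] if res.se_pair is not None else np.nan,
                    "z": res.z_pair[a, b],
                }
            )
    for a in range(j):
        rows.append(
            {
                "level": "item",
                "unit": res.item_labels[a],
                "estimate": res.h_item[a],
                "se": res.se_item[a] if res.se_item is not None else np.nan,
                "z": np.nan,
            }
        )
    rows.append(
        {
            "level": "scale",
            "unit": "scale",
            "estimate": res.h_scale,
            "se": res.se_scale if res.se_scale is not None else np.nan,
            "z": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["level", "unit", "estimate", "se", "z"])


def classify_scale(h_scale: float) -> str:
    """Rule-of-thumb label for H_s; boundaries are closed on the left
    (0.3 -> weak, 0.4 -> moderate, 0.5 -> strong)."""
    if not np.isfinite(h_scale):
        return "undefined"
    if h_scale < 0.3:
        return "unscalable"
    if h_scale < 0.4:
        return "weak"
    if h_scale < 0.5:
        return "moderate"
    return "strong"
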