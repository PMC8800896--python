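"""Synthetic ordinal response data with the structure Mokken analysis assumes.

The generator is a graded response model (GRM): a person with latent health
``theta ~ N(0,1)`` endorses level k or higher on item i with probability
``P(X_i >= k | theta) = logistic(a_i * (theta - b_ik))`` where ``a_i > 0`` is
the item's discrimination and ``b_i1 < ... < b_i,L-1`` its step locations.
Logistic step functions are monotone in theta, so GRM data satisfy
unidimensionality, local independence and latent monotonicity by
construction; equal discriminations additionally give nonintersecting step
functions, i.e. an invariant item ordering.

Two extensions make the generator a complete test harness:

* an EQ-5D-5L preset whose step locations are calibrated (by Gauss-Hermite
  quadrature + root finding; constants committed in ``presets/``) so the
  marginal level distributions match a large published multi-country survey
  sample, and whose anxiety/depression item mixes in a second latent factor
  so its pairwise scalability with the four physical items is depressed;
* controllable model violations (a non-monotone step, a crossing response
  function, a second dimension) for power checks of the manifest diagnostics.

Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .response_data import ResponseMatrix

__all__ = [
    "GrmSpec",
    "ViolationSpec",
    "simulate_grm",
    "eq5d5l_preset",
    "eq5d5l_spec",
    "inject_violation",
    "calibrate_thresholds",
    "marginal_step_probability",
    "EQ5D5L_ITEMS",
    "EQ5D5L_LEVEL_COUNTS",
    "DEFAULT_STRATA",
]

EQ5D5L_ITEMS = ["MO", "SC", "UA", "PD", "AD"]

# Observed level counts (no problems ... extreme problems) per item in the
# multi-country survey sample the preset emulates, N = 7933.  Mobility and
# usual activities are identical as printed in the source table.
EQ5D5L_LEVEL_COUNTS = {
    "MO": [5163, 1707, 771, 244, 48],
    "SC": [6984, 624, 258, 59, 8],
    "UA": [5163, 1707, 771, 244, 48],
    "PD": [2331, 3214, 1595, 683, 110],
    "AD": [3982, 2319, 1088, 383, 161],
}

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(101)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass
class GrmSpec:
    """Parameters of the graded-response generator.

    ``second_loadings[i]`` is the weight of a second, independent standard
    normal factor in item i's effective trait
    ``sqrt(1 - w^2) * theta + w * theta2`` (0 = purely unidimensional); the
    effective trait stays standard normal so marginal calibration is
    unaffected.
    """

    discriminations: np.ndarray          # (J,)
    thresholds: np.ndarray               # (J, L-1), strictly increasing rows
    n_persons: int
    seed: int
    level_min: int = 1
    item_labels: list[str] = field(default_factory=list)
    second_loadings: np.ndarray | None = None
    theta_shift: float = 0.0

    def __post_init__(self) -> None:
        self.discriminations = np.atleast_1d(np.asarray(self.discriminations, float))
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, float))
        j, steps = self.thresholds.shape
        if self.discriminations.shape != (j,):
            raise ValueError("discriminations must have one entry per item")
        if (self.discriminations <= 0).any():
            raise ValueError("discriminations must be positive")
        if (np.diff(self.thresholds, axis=1) <= 0).any():
            raise ValueError("step thresholds must be strictly increasing per item")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not self.item_labels:
            self.item_labels = [f"item{k + 1}" for k in range(j)]
        if self.second_loadings is None:
            self.second_loadings = np.zeros(j)
        else:
            self.second_loadings = np.asarray(self.second_loadings, float)
            if ((self.second_loadings < 0) | (self.second_loadings > 1)).any():
                raise ValueError("second-factor loadings must lie in [0, 1]")

    @property
    def n_items(self) -> int:
        return self.thresholds.shape[0]

    @property
    def level_max(self) -> int:
        return self.level_min + self.thresholds.shape[1]


@dataclass
class ViolationSpec:
    """A controllable departure from the monotone homogeneity model.

    kinds and magnitude bounds:

    * ``nonmonotone_step`` — one step response function dips by ``magnitude``
      (0..1) over a trait window (default: the first step over theta in
      (1.0, 3.5), i.e. the region where that step's curve has saturated —
      a dip on a still-rising stretch is largely invisible after rest-score
      grouping, so the default targets where it is manifestly detectable);
    * ``crossing_irf`` — the target item's discrimination is multiplied by
      ``magnitude`` (> 0), making its response function cross the others';
    * ``second_dimension`` — the target item's responses are driven by a
      second factor with loading ``magnitude`` (0..1).
    """

    kind: str
    item: int | str = 0
    magnitude: float = 0.0
    step: int | None = None                    # nonmonotone_step: step index 0..L-2
    window: tuple[float, float] | None = None  # nonmonotone_step: theta window

    def __post_init__(self) -> None:
        kinds = ("nonmonotone_step", "crossing_irf", "second_dimension")
        if self.kind not in kinds:
            raise ValueError(f"violation kind must be one of {kinds}")
        if self.kind in ("nonmonotone_step", "second_dimension"):
            if not (0.0 <= self.magnitude <= 1.0):
                raise ValueError(f"{self.kind} magnitude must be in [0, 1]")
        elif self.magnitude < 0:
            raise ValueError("crossing_irf magnitude (a multiplier) must be >= 0")


def simulate_grm(
    spec: GrmSpec, violation: ViolationSpec | None = None
) -> ResponseMatrix:
    """Draw an N x J response matrix from the GRM (optionally violated).

    The draw is a single uniform per person-item compared against the
    cumulative step probabilities, which are non-increasing in k, so the
    levels are well defined; seeded draws are byte-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    n, j = spec.n_persons, spec.n_items
    theta = rng.standard_normal(n) + spec.theta_shift
    theta2 = rng.standard_normal(n)  # always drawn: keeps the stream aligned
    loadings = spec.second_loadings.copy()
    a = spec.discriminations.copy()
    tgt = None
    if violation is not None:
        tgt = (
            violation.item
            if isinstance(violation.item, int)
            else spec.item_labels.index(violation.item)
        )
        if violation.kind == "second_dimension":
            loadings[tgt] = violation.magnitude
        elif violation.kind == "crossing_irf" and violation.magnitude > 0:
            a[tgt] = a[tgt] * violation.magnitude
    w = loadings
    eff = np.sqrt(1.0 - w**2)[None, :] * theta[:, None] + w[None, :] * theta2[:, None]
    p = expit(a[None, :, None] * (eff[:, :, None] - spec.thresholds[None, :, :]))
    if violation is not None and violation.kind == "nonmonotone_step":
        k0 = violation.step if violation.step is not None else 0
        t0, t1 = violation.window if violation.window else (1.0, 3.5)
        in_win = (eff[:, tgt] > t0) & (eff[:, tgt] <= t1)
        p[in_win, tgt, k0] = np.clip(p[in_win, tgt, k0] - violation.magnitude, 0.0, 1.0)
        p[:, tgt, :] = np.minimum.accumulate(p[:, tgt, :], axis=1)
    u = rng.uniform(size=(n, j))
    x = spec.level_min + (u[:, :, None] < p).sum(axis=2)
    return ResponseMatrix(
        x.astype(np.int64), spec.level_min, spec.level_max, list(spec.item_labels)
    )


def inject_violation(spec: GrmSpec, v: ViolationSpec) -> ResponseMatrix:
    """Simulate from ``spec`` with violation ``v`` applied.

    Violations are defined at the generator level (they reshape step
    probabilities as functions of the latent trait), so the input is a
    :class:`GrmSpec`; with ``magnitude == 0`` the draw is identical to the
    unviolated generator.
    """
    return simulate_grm(spec, violation=v)


# -- marginal calibration -----------------------------------------------------


def marginal_step_probability(a: float, b: float) -> float:
    """P(X >= k) = integral of logistic(a(t - b)) against the standard normal,
    by Gauss-Hermite quadrature."""
    return float(_GH_WEIGHTS @ expit(a * (_GH_NODES - b)))


def calibrate_thresholds(a: float, cumulative_targets: np.ndarray) -> np.ndarray:
    """Root-find the step locations b_k so that the GRM marginal step
    endorsement rates equal ``cumulative_targets`` (strictly decreasing,
    in (0,1))."""
    targets = np.asarray(cumulative_targets, float)
    if (np.diff(targets) >= 0).any() or ((targets <= 0) | (targets >= 1)).any():
        raise ValueError("cumulative targets must be strictly decreasing within (0,1)")
    return np.array(
        [brentq(lambda b: marginal_step_probability(a, b) - p, -8.0, 8.0) for p in targets]
    )


def _load_preset_constants() -> dict:
    with resources.files("npirt.presets").joinpath("eq5d5l_grm.json").open() as fh:
        return json.load(fh)


def eq5d5l_spec(n_persons: int, seed: int) -> GrmSpec:
    """The EQ-5D-5L GRM spec with committed calibrated constants."""
    c = _load_preset_constants()
    return GrmSpec(
        discriminations=np.array(c["discriminations"]),
        thresholds=np.array([c["thresholds"][it] for it in c["items"]]),
        n_persons=n_persons,
        seed=seed,
        item_labels=list(c["items"]),
        second_loadings=np.array(c["second_loadings"]),
    )


# Default strata emulating the survey's disease-subgroup heterogeneity:
# a healthier-than-average group, a generic chronic-condition group, and a
# depression-like group for which the anxiety/depression item is markedly
# easier to endorse (its step locations shift down).
DEFAULT_STRATA = {
    "healthy": {"weight": 0.25, "theta_shift": -0.9, "item_shifts": {}},
    "chronic": {"weight": 0.60, "theta_shift": 0.25, "item_shifts": {}},
    "depression": {"weight": 0.15, "theta_shift": 0.25, "item_shifts": {"AD": -1.4}},
}


def eq5d5l_preset(
    n_persons: int,
    seed: int,
    groups: dict[str, dict] | None = None,
    group_column: str = "disease",
) -> ResponseMatrix:
    """Synthetic EQ-5D-5L cohort.

    Without ``groups``: one homogeneous cohort whose marginal level shares
    track the published survey sample (level-1 shares MO 65.1%, SC 88.0%,
    UA 65.1%, PD 29.4%, AD 50.2%) and whose AD item carries a second factor.

    With ``groups`` (e.g. :data:`DEFAULT_STRATA`): a mixture of subgroups
    with latent-mean shifts and optional per-item step-location shifts,
    tagged in ``group_labels[group_column]``.
    """
    if n_persons < 100:
        raise ValueError("the preset is meant for cohorts of N >= 100")
    base = eq5d5l_spec(n_persons, seed)
    if not groups:
        return simulate_grm(base)
    names = sorted(groups)
    weights = np.array([groups[g].get("weight", 1.0) for g in names], float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_persons, weights)
    blocks, tags = [], []
    for gi, (name, n_g) in enumerate(zip(names, counts)):
        if n_g == 0:
            continue
        g = groups[name]
        thr = base.thresholds.copy()
        for lab, shift in g.get("item_shifts", {}).items():
            thr[base.item_labels.index(lab)] += shift
        sub = replace(
            base,
            thresholds=thr,
            n_persons=int(n_g),
            seed=int(rng.integers(0, 2**31 - 1)),
            theta_shift=float(g.get("theta_shift", 0.0)),
            item_labels=list(base.item_labels),
        )
        blocks.append(simulate_grm(sub).values)
        tags.extend([name] * int(n_g))
    values = np.vstack(blocks)
    perm = np.random.default_rng(seed + 1).permutation(len(values))
    return ResponseMatrix(
        values[perm],
        base.level_min,
        base.level_max,
        list(base.item_labels),
        {group_column: np.asarray(tags, dtype=object)[perm]},
    )
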