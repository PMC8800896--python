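"""Independent oracles for the maximum-covariance normalizer.

Both stay deliberately independent of the package's implementation: one
enumerates couplings outright, the other solves the transportation linear
program.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def expand(marginal: np.ndarray) -> np.ndarray:
    """Counts over levels 1..L -> the sorted sample vector."""
    return np.repeat(np.arange(1, len(marginal) + 1), marginal).astype(float)


def max_cov_enumeration(marginal_i, marginal_j) -> float:
    """Maximum population covariance over every coupling of the two
    marginals, by enumerating all distinct pairings of the sample vectors."""
    x = expand(np.asarray(marginal_i))
    y = expand(np.asarray(marginal_j))
    n = len(x)
    assert n == len(y) and n <= 8, "enumeration oracle is for tiny N"
    ex, ey = x.mean(), y.mean()
    best = -np.inf
    for perm in set(itertools.permutations(y)):
        best = max(best, float(np.dot(x, perm)) / n - ex * ey)
    return best


def max_cov_lp(marginal_i, marginal_j) -> float:
    """Maximum covariance via the transportation LP: maximize sum p_ab*a*b
    over joint distributions with the given marginals."""
    fi = np.asarray(marginal_i, dtype=float)
    fj = np.asarray(marginal_j, dtype=float)
    n = fi.sum()
    li = np.arange(1, len(fi) + 1, dtype=float)
    lj = np.arange(1, len(fj) + 1, dtype=float)
    c = -(li[:, None] * lj[None, :]).ravel()  # maximize => minimize negative
    a_eq = []
    b_eq = []
    for a in range(len(fi)):
        row = np.zeros((len(fi), len(fj)))
        row[a, :] = 1
        a_eq.append(row.ravel())
        b_eq.append(fi[a] / n)
    for b in range(len(fj)):
        row = np.zeros((len(fi), len(fj)))
        row[:, b] = 1
        a_eq.append(row.ravel())
        b_eq.append(fj[b] / n)
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    assert res.success
    exy = -res.fun
    return exy - (fi @ li / n) * (fj @ lj / n)
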