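"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from npirt.response_data import ResponseMatrix
from npirt.synthetic import GrmSpec, simulate_grm

# the standard monotone-homogeneity-true fixture: five 5-level items,
# equal discrimination 2, equally spaced step locations
STD_OFFSETS = np.array([-1.2, -0.4, 0.4, 1.2])
STD_LOCATIONS = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def std_spec(n: int = 5000, seed: int = 7, a: float = 2.0) -> GrmSpec:
    return GrmSpec(
        discriminations=np.full(5, a),
        thresholds=STD_LOCATIONS[:, None] + STD_OFFSETS[None, :],
        n_persons=n,
        seed=seed,
    )


@pytest.fixture(scope="session")
def grm_matrix() -> ResponseMatrix:
    """One MHM-true sample at N=5000 reused across read-only tests."""
    return simulate_grm(std_spec())


def guttman_matrix(n: int = 200, n_items: int = 5, levels: int = 5) -> ResponseMatrix:
    """Deterministic perfect Guttman (comonotonic) data.

    Person p's standing is p/n; item i's step cutoffs are nested so every
    pair of columns is comonotonic and every H coefficient equals 1.
    """
    u = np.linspace(0.02, 0.98, n)
    x = np.empty((n, n_items), dtype=np.int64)
    for i in range(n_items):
        # item difficulty increases with i; step k needs u > cut
        cuts = np.linspace(0.08, 0.92, levels - 1) + 0.015 * i
        x[:, i] = 1 + (u[:, None] > cuts[None, :]).sum(axis=1)
    return ResponseMatrix(x, 1, levels)
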