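"""MIIO checks, backward selection, H^T and paired IRFs."""

import numpy as np
import pytest

from npirt.item_ordering import (
    backward_selection,
    check_miio,
    classify_ht,
    coefficient_ht,
    paired_irf,
)
from npirt.response_data import ConfigError, ResponseMatrix
from npirt.scalability import compute_h_scale
from npirt.synthetic import GrmSpec, ViolationSpec, simulate_grm

from .conftest import guttman_matrix

# narrow steps + tight item locations: a tripled discrimination makes the
# target item's response function cross its neighbours' inside the
# observable rest-score range
CROSS_OFFSETS = np.array([-0.75, -0.25, 0.25, 0.75])
CROSS_LOCATIONS = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])


def cross_spec(n=5000, seed=0, a=1.2):
    return GrmSpec(
        np.full(5, a), CROSS_LOCATIONS[:, None] + CROSS_OFFSETS[None, :], n, seed
    )


class TestCheckMiio:
    def test_well_separated_grm_clean(self, grm_matrix):
        rep = check_miio(grm_matrix)
        assert rep.total_violations == 0
        assert (rep.item_summary["crit"] == 0).all()

    def test_order_is_by_descending_mean(self, grm_matrix):
        rep = check_miio(grm_matrix)
        means = [rep.item_means[l] for l in rep.item_order]
        assert means == sorted(means, reverse=True)

    def test_crossing_item_flagged(self):
        m = simulate_grm(cross_spec(seed=5), ViolationSpec("crossing_irf", item=2, magnitude=3.0))
        rep = check_miio(m)
        target = m.item_labels[2]
        assert sum(p.violations for p in rep.pairs if target in (p.easy, p.hard)) >= 1

    def test_huge_minvi_silences(self):
        m = simulate_grm(cross_spec(seed=6), ViolationSpec("crossing_irf", item=2, magnitude=3.0))
        rep = check_miio(m, minvi_pair=4.0)
        assert rep.total_violations == 0

    def test_two_items_rejected(self):
        m = ResponseMatrix(np.random.default_rng(0).integers(1, 6, (100, 2)))
        with pytest.raises(ConfigError, match="3 items"):
            check_miio(m)

    def test_default_minvi_scales_with_levels(self, grm_matrix):
        rep = check_miio(grm_matrix)
        assert rep.minvi_pair == pytest.approx(4 * 0.03)


class TestBackwardSelection:
    def test_injected_item_removed_first(self):
        m = simulate_grm(cross_spec(seed=7), ViolationSpec("crossing_irf", item=2, magnitude=3.0))
        rep = backward_selection(m)
        assert rep.removed_items and rep.removed_items[0] == m.item_labels[2]

    def test_clean_fixture_removes_nothing(self, grm_matrix):
        rep = backward_selection(grm_matrix)
        assert rep.removed_items == []

    def test_fixed_point(self):
        m = simulate_grm(cross_spec(seed=8), ViolationSpec("crossing_irf", item=2, magnitude=3.0))
        rep = backward_selection(m)
        survivors = [l for l in m.item_labels if l not in rep.removed_items]
        if len(survivors) >= 3:
            again = check_miio(m.subset_items(survivors))
            assert again.total_violations == 0


class TestCoefficientHT:
    def test_transpose_identity(self):
        rng = np.random.default_rng(9)
        m = ResponseMatrix(rng.integers(1, 6, size=(40, 5)))
        keep = m.values.std(axis=1) > 0
        transposed = ResponseMatrix(m.values[keep].T)
        assert coefficient_ht(m) == pytest.approx(
            compute_h_scale(transposed).h_scale
        )

    def test_permutation_invariance(self, grm_matrix):
        ht = coefficient_ht(grm_matrix)
        rng = np.random.default_rng(10)
        pp = rng.permutation(grm_matrix.n_persons)
        pi = rng.permutation(grm_matrix.n_items)
        shuffled = ResponseMatrix(grm_matrix.values[pp][:, pi])
        assert coefficient_ht(shuffled) == pytest.approx(ht)

    def test_separated_grm_high_accuracy(self, grm_matrix):
        assert coefficient_ht(grm_matrix) > 0.5
        assert classify_ht(coefficient_ht(grm_matrix)) == "high"

    def test_constant_persons_removed_or_undefined(self):
        assert np.isnan(coefficient_ht(ResponseMatrix(np.full((20, 4), 3))))
        # constant persons are dropped, the rest still defined
        x = np.vstack([np.full((5, 4), 2), np.random.default_rng(1).integers(1, 6, (30, 4))])
        assert np.isfinite(coefficient_ht(ResponseMatrix(x)))

    def test_guttman_persons_perfectly_ordered(self):
        m = guttman_matrix(n=100)
        nonconstant = m.values.std(axis=1) > 0
        assert coefficient_ht(m) == pytest.approx(1.0)
        assert nonconstant.sum() >= 2


class TestPairedIrf:
    def test_duplicate_items_identical_curves(self):
        rng = np.random.default_rng(12)
        x = rng.integers(1, 6, size=(800, 1))
        extra = rng.integers(1, 6, size=(800, 2))
        m = ResponseMatrix(np.hstack([x, x, extra]), item_labels=["a", "b", "c", "d"])
        t = paired_irf(m, "a", "b")
        np.testing.assert_allclose(t["irf_a"], t["irf_b"])

    def test_easy_dominates_hard_without_crossing(self, grm_matrix):
        rep = check_miio(grm_matrix)
        easy, hard = rep.item_order[0], rep.item_order[-1]
        t = paired_irf(grm_matrix, easy, hard)
        assert (t[f"irf_{easy}"].to_numpy() >= t[f"irf_{hard}"].to_numpy() - 0.02).all()

    def test_crossing_fixture_curves_cross(self):
        m = simulate_grm(
            cross_spec(n=20_000, seed=13), ViolationSpec("crossing_irf", item=2, magnitude=3.0)
        )
        target = m.item_labels[2]
        crossed = False
        for other in (1, 3):
            t = paired_irf(m, target, other)
            d = t[f"irf_{target}"].to_numpy() - t[f"irf_{m.item_labels[other]}"].to_numpy()
            if (d > 0).any() and (d < 0).any():
                crossed = True
        assert crossed
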