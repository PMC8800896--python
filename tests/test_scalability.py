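"""Loevinger H coefficients: normalizer, ratios, SEs and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npirt.response_data import ResponseMatrix, ValidationError
from npirt.scalability import (
    classify_scale,
    compute_h_item,
    compute_h_pair,
    compute_h_scale,
    max_covariance,
    standard_errors,
)
from npirt.synthetic import simulate_grm

from .conftest import guttman_matrix, std_spec
from .oracles import max_cov_enumeration


class TestMaxCovariance:
    @pytest.mark.parametrize(
        "fi, fj, expected",
        [
            ([2, 2], [2, 2], 0.25),
            ([4, 0], [2, 2], 0.0),          # constant marginal
            ([1, 1, 1], [1, 1, 1], 2 / 3),  # comonotonic (1,1)(2,2)(3,3)
        ],
    )
    def test_known_values(self, fi, fj, expected):
        assert max_covariance(fi, fj) == pytest.approx(expected)

    def test_unequal_totals_rejected(self):
        with pytest.raises(ValidationError):
            max_covariance([2, 2], [1, 2])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        levels = int(rng.integers(2, 5))
        fi = rng.multinomial(n, np.ones(levels) / levels)
        fj = rng.multinomial(n, np.ones(levels) / levels)
        assert max_covariance(fi, fj) == pytest.approx(max_cov_enumeration(fi, fj))

    def test_dominates_observed_covariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.integers(1, 6, 40)
            y = rng.integers(1, 6, 40)
            cov = float(np.cov(x, y, bias=True)[0, 1])
            cm = max_covariance(np.bincount(x, minlength=6)[1:], np.bincount(y, minlength=6)[1:])
            assert cm >= cov - 1e-12


class TestHCoefficients:
    def test_comonotonic_pair_is_one(self):
        m = ResponseMatrix(np.array([[1, 1], [1, 1], [2, 2], [2, 2]]))
        assert compute_h_pair(m, 0, 1) == pytest.approx(1.0)

    def test_zero_covariance_pair(self):
        m = ResponseMatrix(np.array([[1, 1], [1, 2], [2, 1], [2, 2]]))
        assert compute_h_pair(m, 0, 1) == pytest.approx(0.0)

    def test_guttman_data_all_ones(self):
        res = compute_h_scale(guttman_matrix())
        assert np.allclose(res.h_item, 1.0)
        assert res.h_scale == pytest.approx(1.0)
        off = res.h_pair[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_two_items_all_equal(self):
        rng = np.random.default_rng(2)
        m = ResponseMatrix(rng.integers(1, 6, size=(200, 2)))
        h12 = compute_h_pair(m, 0, 1)
        res = compute_h_scale(m)
        assert res.h_item[0] == pytest.approx(h12)
        assert res.h_item[1] == pytest.approx(h12)
        assert res.h_scale == pytest.approx(h12)
        assert compute_h_item(m, 0) == pytest.approx(h12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(11)
        m = ResponseMatrix(rng.integers(1, 6, size=(20_000, 2)))
        assert abs(compute_h_pair(m, 0, 1)) < 0.02

    def test_grm_items_sufficiently_scalable(self, grm_matrix):
        res = compute_h_scale(grm_matrix)
        assert (res.h_item > 0.3).all()

    def test_h_scale_between_item_extremes(self, grm_matrix):
        res = compute_h_scale(grm_matrix)
        assert res.h_item.min() - 1e-12 <= res.h_scale <= res.h_item.max() + 1e-12

    def test_level_shift_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 5, size=(300, 4))
        base = compute_h_scale(ResponseMatrix(x, 1, 6))
        shifted = x.copy()
        shifted[:, 2] += 2  # constant shift of one item's levels
        res = compute_h_scale(ResponseMatrix(shifted, 1, 6))
        assert np.allclose(res.h_item, base.h_item, equal_nan=True)
        assert res.h_scale == pytest.approx(base.h_scale)

    def test_negative_pair_reported_as_violation(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 6, 500)
        m = ResponseMatrix(np.column_stack([a, 6 - a, rng.integers(1, 6, 500)]))
        res = compute_h_scale(m)
        pairs = {(x, y) for x, y, _ in res.negative_pairs()}
        assert ("item1", "item2") in pairs

    def test_zero_variance_item_flagged_not_dropped(self):
        m = ResponseMatrix(np.column_stack([np.full(50, 3), np.arange(50) % 5 + 1]))
        res = compute_h_scale(m)
        assert res.undefined_items == [0]
        assert np.isnan(res.h_item[0])
        assert len(res.h_item) == 2


class TestBootstrapSE:
    def test_deterministic_under_seed(self, grm_matrix):
        a = standard_errors(grm_matrix, B=50, seed=9)
        b = standard_errors(grm_matrix, B=50, seed=9)
        assert np.array_equal(a.se_item, b.se_item)
        assert a.se_scale == b.se_scale

    def test_b_too_small(self, grm_matrix):
        with pytest.raises(ValueError):
            standard_errors(grm_matrix, B=1)

    def test_constant_dataset_flagged_with_zero_se(self):
        m = ResponseMatrix(np.full((40, 3), 2))
        res = standard_errors(m, B=20, seed=0)
        assert res.undefined_items == [0, 1, 2]
        assert np.all(res.se_item == 0)

    def test_se_shrinks_with_n(self):
        big = simulate_grm(std_spec(n=4000, seed=21))
        small = simulate_grm(std_spec(n=1000, seed=22))
        se_big = standard_errors(big, B=60, seed=5).se_scale
        se_small = standard_errors(small, B=60, seed=5).se_scale
        assert se_big < se_small


class TestClassification:
    @pytest.mark.parametrize(
        "h, label",
        [
            (0.559, "strong"),
            (0.299, "unscalable"),
            (0.45, "moderate"),
            (0.3, "weak"),
            (0.4, "moderate"),
            (0.5, "strong"),
            (float("nan"), "undefined"),
        ],
    )
    def test_boundaries(self, h, label):
        assert classify_scale(h) == label
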