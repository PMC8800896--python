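"""Generator contracts: reproducibility, marginal calibration, violations."""

import json
from importlib import resources

import numpy as np
import pytest

from npirt.response_data import ResponseMatrix
from npirt.scalability import compute_h_scale
from npirt.synthetic import (
    DEFAULT_STRATA,
    EQ5D5L_ITEMS,
    EQ5D5L_LEVEL_COUNTS,
    GrmSpec,
    ViolationSpec,
    calibrate_thresholds,
    eq5d5l_preset,
    eq5d5l_spec,
    inject_violation,
    marginal_step_probability,
    simulate_grm,
)

from .conftest import std_spec


class TestSimulateGrm:
    def test_reproducible(self):
        a = simulate_grm(std_spec(n=500, seed=42))
        b = simulate_grm(std_spec(n=500, seed=42))
        assert np.array_equal(a.values, b.values)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GrmSpec(np.array([2.0]), np.array([[0.0, -0.5, 0.5, 1.0]]), 100, 0)

    def test_huge_discrimination_near_guttman(self):
        m = simulate_grm(std_spec(n=3000, seed=2, a=50.0))
        assert compute_h_scale(m).h_scale > 0.95

    def test_marginals_match_quadrature(self):
        spec = std_spec(n=5000, seed=19)
        m = simulate_grm(spec)
        for i in range(5):
            for k, b in enumerate(spec.thresholds[i]):
                p = marginal_step_probability(2.0, b)
                emp = (m.values[:, i] >= 2 + k).mean()
                se = np.sqrt(p * (1 - p) / spec.n_persons)
                assert abs(emp - p) < 2.5 * se + 1e-9


class TestEq5d5lPreset:
    def test_committed_constants_match_fresh_calibration(self):
        with resources.files("npirt.presets").joinpath("eq5d5l_grm.json").open() as fh:
            c = json.load(fh)
        for it, a in zip(c["items"], c["discriminations"]):
            fresh = calibrate_thresholds(a, np.array(c["cumulative_targets"][it]))
            np.testing.assert_allclose(fresh, c["thresholds"][it], atol=1e-5)

    def test_level_one_shares_match_survey(self):
        m = eq5d5l_preset(50_000, 11)
        for i, it in enumerate(EQ5D5L_ITEMS):
            counts = np.array(EQ5D5L_LEVEL_COUNTS[it], float)
            target = counts[0] / counts.sum()
            share = (m.values[:, i] == 1).mean()
            assert abs(share - target) < 0.02, it

    def test_ad_weakest_and_second_factor_depresses_pairs(self):
        m = eq5d5l_preset(20_000, 4)
        res = compute_h_scale(m)
        ad = m.item_index("AD")
        physical = [i for i in range(5) if i != ad]
        assert res.h_item[ad] < min(res.h_item[physical])
        ad_pairs = [res.h_pair[ad, i] for i in physical]
        phys_pairs = [
            res.h_pair[a, b] for a in physical for b in physical if a < b
        ]
        assert max(ad_pairs) < min(phys_pairs)

    def test_dropping_ad_strengthens_scale(self):
        m = eq5d5l_preset(20_000, 4)
        full = compute_h_scale(m).h_scale
        reduced = compute_h_scale(m.drop_items(["AD"])).h_scale
        assert reduced > full

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            eq5d5l_preset(50, 0)

    def test_stratified_heterogeneity(self):
        m = eq5d5l_preset(8000, 21, groups=DEFAULT_STRATA)
        assert set(m.group_labels["disease"]) == {"healthy", "chronic", "depression"}
        by = {tag: sub for tag, sub in m.iter_groups("disease")}
        ad = m.item_index("AD")
        # depression stratum endorses AD more than the generic chronic one
        assert by["depression"].values[:, ad].mean() > by["chronic"].values[:, ad].mean() + 0.5
        # healthy stratum is healthiest overall
        assert by["healthy"].level_sum_score().mean() < by["chronic"].level_sum_score().mean()


class TestViolations:
    def test_magnitude_zero_identical_to_base(self):
        spec = std_spec(n=1000, seed=23)
        base = simulate_grm(spec)
        for kind in ("nonmonotone_step", "crossing_irf", "second_dimension"):
            mag = 1.0 if kind == "crossing_irf" else 0.0
            v = ViolationSpec(kind, item=2, magnitude=mag)
            assert np.array_equal(inject_violation(spec, v).values, base.values)

    def test_bad_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            ViolationSpec("nonmonotone_step", magnitude=1.5)
        with pytest.raises(ValueError):
            ViolationSpec("second_dimension", magnitude=-0.1)
        with pytest.raises(ValueError):
            ViolationSpec("unknown_kind")

    def test_second_dimension_decouples_item(self):
        spec = std_spec(n=20_000, seed=24)
        base = compute_h_scale(simulate_grm(spec))
        violated = compute_h_scale(
            inject_violation(spec, ViolationSpec("second_dimension", item=2, magnitude=0.9))
        )
        assert violated.h_item[2] < base.h_item[2] - 0.2
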