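"""Profile codec, level sum score, rest scores and delimited-text I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npirt.response_data import (
    ConfigError,
    ParseError,
    ReaderConfig,
    ResponseMatrix,
    ValidationError,
    decode_profile,
    encode_profile,
    enumerate_profiles,
    read_responses,
    write_scores,
)


class TestProfileCodec:
    @pytest.mark.parametrize(
        "levels, digits",
        [((1, 1, 1, 1, 1), "11111"), ((5, 5, 5, 5, 5), "55555"), ((1, 1, 1, 2, 1), "11121")],
    )
    def test_encode(self, levels, digits):
        assert encode_profile(levels).digits == digits

    def test_out_of_bounds_names_item(self):
        with pytest.raises(ValidationError, match="item 3"):
            encode_profile((1, 1, 1, 6, 1))

    def test_enumeration_is_complete_and_distinct(self):
        profiles = {p.digits for p in enumerate_profiles(5)}
        assert len(profiles) == 5**5 == 3125

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=8))
    @settings(deadline=None)
    def test_roundtrip(self, levels):
        assert decode_profile(encode_profile(levels)) == tuple(levels)


class TestScores:
    @pytest.mark.parametrize(
        "profile, lss", [("11111", 5), ("55555", 25), ("11121", 6)]
    )
    def test_level_sum_score(self, profile, lss):
        m = ResponseMatrix(np.array([decode_profile(profile)] * 2))
        assert (m.level_sum_score() == lss).all()

    def test_rest_score_examples(self):
        m = ResponseMatrix(
            np.array([decode_profile("11121"), decode_profile("55555")]),
            item_labels=["MO", "SC", "UA", "PD", "AD"],
        )
        assert m.rest_scores(["PD"]).tolist() == [4, 20]
        assert m.rest_scores(["MO"]).tolist() == [5, 20]

    def test_rest_score_exclude_all_is_error(self):
        m = ResponseMatrix(np.ones((3, 5), dtype=int))
        with pytest.raises(ConfigError):
            m.rest_scores(range(5))
        with pytest.raises(ConfigError):
            m.rest_scores([])

    @given(
        st.integers(0, 2**31 - 1),
        st.integers(2, 6),
        st.integers(1, 30),
    )
    @settings(deadline=None, max_examples=30)
    def test_lss_permutation_invariant_and_rest_identity(self, seed, j, n):
        rng = np.random.default_rng(seed)
        m = ResponseMatrix(rng.integers(1, 6, size=(n, j)))
        lss = m.level_sum_score()
        perm = rng.permutation(j)
        assert (ResponseMatrix(m.values[:, perm]).level_sum_score() == lss).all()
        for i in range(j):
            assert (m.rest_scores([i]) + m.values[:, i] == lss).all()

    def test_lss_bounds(self):
        rng = np.random.default_rng(0)
        m = ResponseMatrix(rng.integers(1, 6, size=(50, 5)))
        lss = m.level_sum_score()
        assert lss.min() >= 5 and lss.max() <= 25


class TestValidation:
    def test_level_bounds_enforced(self):
        with pytest.raises(ValidationError):
            ResponseMatrix(np.array([[0, 1], [1, 2]]))

    def test_min_shape(self):
        with pytest.raises(ValidationError):
            ResponseMatrix(np.array([[1], [2]]))  # J = 1

    def test_group_length_checked(self):
        with pytest.raises(ValidationError):
            ResponseMatrix(np.ones((3, 2), dtype=int), group_labels={"g": np.array(["a"])})


class TestIO:
    def _write(self, tmp_path, text, name="data.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_well_formed(self, tmp_path):
        p = self._write(tmp_path, "MO,SC,grp\n1,2,a\n3,4,b\n5,1,a\n")
        m = read_responses(p, ReaderConfig(["MO", "SC"], group_columns=["grp"]))
        assert m.n_persons == 3 and m.n_items == 2
        assert m.group_labels["grp"].tolist() == ["a", "b", "a"]

    def test_missing_cell_listwise(self, tmp_path, caplog):
        p = self._write(tmp_path, "MO,SC\n1,2\n3,\n5,1\n")
        with caplog.at_level("WARNING"):
            m = read_responses(p, ReaderConfig(["MO", "SC"]))
        assert m.n_persons == 2
        assert "dropped 1" in caplog.text

    def test_out_of_bounds_level(self, tmp_path):
        p = self._write(tmp_path, "MO,SC\n0,2\n")
        with pytest.raises(ValidationError):
            read_responses(p, ReaderConfig(["MO", "SC"]))

    def test_non_integer_cell(self, tmp_path):
        p = self._write(tmp_path, "MO,SC\n1,x\n")
        with pytest.raises(ParseError, match="SC"):
            read_responses(p, ReaderConfig(["MO", "SC"]))

    def test_unknown_column(self, tmp_path):
        p = self._write(tmp_path, "MO,SC\n1,2\n")
        with pytest.raises(ConfigError, match="XX"):
            read_responses(p, ReaderConfig(["MO", "XX"]))

    def test_tsv_autodetect(self, tmp_path):
        p = self._write(tmp_path, "MO\tSC\n1\t2\n2\t3\n", name="data.tsv")
        m = read_responses(p, ReaderConfig(["MO", "SC"]))
        assert m.values.tolist() == [[1, 2], [2, 3]]

    def test_score_writer(self, tmp_path):
        m = ResponseMatrix(np.array([[1, 2], [3, 4]]), item_labels=["a", "b"])
        out = tmp_path / "scores.tsv"
        write_scores(m, out)
        t = pd.read_csv(out, sep="\t")
        assert list(t.columns) == ["person", "lss", "rest_a", "rest_b"]
        assert t["lss"].tolist() == [3, 7]
        assert t["rest_a"].tolist() == [2, 4]
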