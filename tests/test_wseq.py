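"""Weighted-sequence model: probability arithmetic, validation, I/O."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtandem import (
    ParseError,
    Threshold,
    ValidationError,
    WeightedPosition,
    WeightedSequence,
    char_weight,
    factor_weight,
    is_real_factor,
    msa_to_weighted,
    parse_weighted_sequence,
    write_weighted_sequence,
)
from conftest import random_ws


class TestCharWeight:
    @pytest.mark.parametrize(
        "i, c, expected",
        [
            (2, "G", 1.0),   # deterministic position, implicit weight 1
            (1, "T", 0.0),   # absent character
            (3, "C", 0.4),
            (1, "A", 0.5),
            (4, "T", 0.25),
        ],
    )
    def test_worked_example(self, X, i, c, expected):
        assert char_weight(X, i, c) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range(self, X):
        with pytest.raises(IndexError):
            char_weight(X, 0, "A")
        with pytest.raises(IndexError):
            char_weight(X, 6, "A")


class TestFactorWeight:
    @pytest.mark.parametrize(
        "i, f, expected",
        [
            (2, "GAT", 0.15),  # 1 * 0.6 * 0.25
            (1, "AGA", 0.3),   # 0.5 * 1 * 0.6
            (3, "CAC", 0.1),   # 0.4 * 0.25 * 1
            (1, "", 1.0),      # empty product
            (1, "TGA", 0.0),   # T absent at position 1
        ],
    )
    def test_worked_example(self, X, i, f, expected):
        assert factor_weight(X, i, f) == pytest.approx(expected, abs=1e-12)

    def test_overrun_raises(self, X):
        with pytest.raises(IndexError):
            factor_weight(X, 4, "CCC")

    def test_length_one_equals_char_weight(self, X):
        for i in range(1, X.n + 1):
            for c in "ACGT":
                assert factor_weight(X, i, c) == char_weight(X, i, c)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10**6), data=st.data())
    def test_anti_monotone_in_extension(self, seed, data):
        """Appending a character can never raise the cumulative weight."""
        ws = random_ws(seed)
        i = data.draw(st.integers(1, ws.n))
        max_len = ws.n - i + 1
        f_len = data.draw(st.integers(0, max_len - 1))
        f = "".join(
            data.draw(st.sampled_from(ws.position(i + j).chars))
            for j in range(f_len)
        )
        sigma = data.draw(st.sampled_from(sorted(ws.alphabet)))
        assert factor_weight(ws, i, f + sigma) <= factor_weight(ws, i, f) + 1e-15


class TestRealFactor:
    def test_boundary_equality_counts(self, X, t03):
        assert is_real_factor(X, 1, "AGA", t03)  # exactly 0.3 >= 0.3

    def test_below_threshold(self, X, t03):
        assert not is_real_factor(X, 3, "CAC", t03)

    def test_single_char_at_own_prob(self):
        ws = WeightedSequence([WeightedPosition({"A": 0.7, "C": 0.3})])
        assert is_real_factor(ws, 1, "C", Threshold(0.3))

    def test_threshold_bounds(self):
        with pytest.raises(ValidationError):
            Threshold(0.0)
        with pytest.raises(ValidationError):
            Threshold(1.5)
        assert Threshold.from_k(2.0).min_prob == 0.5
        assert Threshold(0.25).k == 4.0


class TestPositionValidation:
    def test_zero_weights_dropped(self):
        p = WeightedPosition({"A": 1.0, "C": 0.0})
        assert p.chars == ("A",)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            WeightedPosition({"A": 1.2, "C": -0.2})

    def test_sum_tolerance(self):
        WeightedPosition({"A": 0.5, "C": 0.5 + 5e-7})  # inside tolerance
        with pytest.raises(ValidationError):
            WeightedPosition({"A": 0.5, "C": 0.6})


class TestWseqFormat:
    def test_parse_worked_example_fixture(self, X):
        text = (
            "# comment\n"
            "1\tA:0.5,C:0.25,G:0.25\n"
            "2\tG:1.0\n"
            "3\tA:0.6,C:0.4\n"
            "4\tA:0.25,C:0.25,G:0.25,T:0.25\n"
            "5\tC:1.0\n"
        )
        ws = parse_weighted_sequence(text)
        assert ws.n == 5
        assert ws.alphabet == frozenset("ACGT")
        assert ws == X

    def test_single_position(self):
        ws = parse_weighted_sequence("1\tA:1.0\n")
        assert ws.n == 1
        assert ws.char_weight(1, "A") == 1.0

    @pytest.mark.parametrize(
        "text, exc",
        [
            ("1\tA:0.5,C:0.6\n", ValidationError),   # sums to 1.1
            ("1\tA:-0.1,C:1.1\n", ValidationError),  # negative
            ("1\tA;1.0\n", ParseError),              # malformed entry
            ("2\tA:1.0\n", ParseError),              # index out of order
            ("", ParseError),                        # empty input
        ],
    )
    def test_rejects_bad_input(self, text, exc):
        with pytest.raises(exc):
            parse_weighted_sequence(text)

    def test_parse_error_carries_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_weighted_sequence("1\tA:1.0\n2\tbroken\n")

    def test_weight_one_written_explicitly(self):
        ws = WeightedSequence.from_string("C")
        assert write_weighted_sequence(ws) == "1\tC:1.0\n"

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10**6))
    def test_round_trip(self, seed):
        ws = random_ws(seed, max_chars=3)
        again = parse_weighted_sequence(write_weighted_sequence(ws))
        assert again.approx_equal(ws, tol=1e-9)
        assert write_weighted_sequence(again) == write_weighted_sequence(ws)


class TestMsaToWeighted:
    def test_unanimous_columns(self):
        ws = msa_to_weighted(["AC", "AC"])
        assert ws.char_weight(1, "A") == 1.0
        assert ws.char_weight(2, "C") == 1.0

    def test_even_split(self):
        ws = msa_to_weighted(["AC", "GC"])
        assert ws.char_weight(1, "A") == pytest.approx(0.5)
        assert ws.char_weight(1, "G") == pytest.approx(0.5)
        assert ws.char_weight(2, "C") == 1.0

    def test_gaps_excluded_from_denominator(self):
        ws = msa_to_weighted(["A-", "AC", "AC"])
        assert ws.char_weight(1, "A") == 1.0
        assert ws.char_weight(2, "C") == 1.0
        assert "-" not in ws.alphabet

    def test_identical_rows_all_weight_one(self):
        ws = msa_to_weighted(["GATTACA"] * 5)
        assert all(
            ws.char_weight(i + 1, c) == 1.0 for i, c in enumerate("GATTACA")
        )

    def test_column_sums_normalized(self):
        ws = msa_to_weighted(["ACG", "ATG", "CTG", "ATT"])
        for i in range(1, ws.n + 1):
            assert math.fsum(ws.position(i).weights.values()) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rows", [["AC", "ACG"], ["--", "--"], []])
    def test_rejects_bad_alignments(self, rows):
        with pytest.raises(ValidationError):
            msa_to_weighted(rows)
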