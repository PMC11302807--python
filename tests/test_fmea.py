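"""FMEA engine: exact rational scoring, risk matrix, ranking, audits."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careflow.fmea import (
    FailureMode,
    Register,
    RiskMatrix,
    audit_register,
    classify,
    consensus,
    default_matrix,
    display_round,
    parse_score,
    rpn,
    summarize,
    top_fraction,
)


class TestConsensus:
    def test_mean_of_three_raters_is_exact_third(self):
        assert consensus([5, 5, 6]) == Fraction(16, 3)
        assert display_round(consensus([5, 5, 6])) == 5.33

    def test_singleton_mean(self):
        assert consensus([4]) == 4

    def test_mean_of_4_4_5(self):
        assert consensus([4, 4, 5]) == Fraction(13, 3)
        assert display_round(consensus([4, 4, 5])) == 4.33

    def test_agreed_value_path(self):
        assert consensus([7], method="agreed_value") == 7
        with pytest.raises(ValueError):
            consensus([7, 8], method="agreed_value")

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            consensus([])
        with pytest.raises(ValueError):
            consensus([0, 5])
        with pytest.raises(ValueError):
            consensus([5, 11])


class TestRPN:
    @pytest.mark.parametrize(
        "O, S, D, exact, shown",
        [
            (7, 8, 4, Fraction(224), 224.0),
            (4, Fraction(16, 3), Fraction(13, 3), Fraction(832, 9), 92.44),
            (Fraction(8, 3), 5, Fraction(20, 3), Fraction(800, 9), 88.89),
            (1, 1, 1, Fraction(1), 1.0),
        ],
    )
    def test_exact_products_and_display(self, O, S, D, exact, shown):
        value = rpn(O, S, D)
        assert value == exact
        assert display_round(value) == shown

    def test_rounded_displays_would_be_wrong(self):
        # multiplying the two-decimal displays gives 92.32, not the
        # published 92.44 -- the motivation for exact rationals
        assert round(4 * 5.33 * 4.33, 2) == 92.32
        assert display_round(rpn(4, Fraction(16, 3), Fraction(13, 3))) == 92.44

    @given(
        st.integers(1, 10), st.integers(1, 10), st.integers(1, 10)
    )
    def test_integer_scores_give_integer_rpn(self, o, s, d):
        value = rpn(Fraction(o), Fraction(s), Fraction(d))
        assert value.denominator == 1

    @given(
        st.integers(3, 30), st.integers(3, 30), st.integers(3, 30)
    )
    def test_third_valued_scores_give_twentyseventh_multiples(self, o, s, d):
        value = rpn(Fraction(o, 3), Fraction(s, 3), Fraction(d, 3))
        assert (value * 27).denominator == 1


class TestParseScore:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            ("7", Fraction(7)),
            ("5.33", Fraction(16, 3)),
            ("2.67", Fraction(8, 3)),
            ("8.67", Fraction(26, 3)),
            ("1.33", Fraction(4, 3)),
            ("16/3", Fraction(16, 3)),
            ("5;5;6", Fraction(16, 3)),
            ("4.5", Fraction(9, 2)),
        ],
    )
    def test_thirds_mode(self, cell, expected):
        assert parse_score(cell) == expected

    def test_decimal_literal_mode_is_opt_in(self):
        assert parse_score("5.33", mode="decimal") == Fraction(533, 100)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            parse_score("0.5")
        with pytest.raises(ValueError):
            parse_score("11")


class TestRiskMatrix:
    def test_severity_override_regardless_of_occurrence(self, matrix):
        assert matrix.level(9, 1) == "high"
        assert matrix.level(10, 1) == "high"

    def test_minimal_corner_is_low(self, matrix):
        assert matrix.level(1, 1) == "low"

    def test_raising_occurrence_never_lowers_level(self, matrix):
        rank = {"low": 0, "medium": 1, "high": 2}
        for s in range(1, 11):
            levels = [rank[matrix.level(s, o)] for o in range(1, 11)]
            assert levels == sorted(levels)

    def test_raising_severity_never_lowers_level(self, matrix):
        rank = {"low": 0, "medium": 1, "high": 2}
        for o in range(1, 11):
            levels = [rank[matrix.level(s, o)] for s in range(1, 11)]
            assert levels == sorted(levels)

    def test_fractional_scores_are_ceiled_conservatively(self, matrix):
        # S = 8.67 rounds up to the override row
        assert matrix.level(Fraction(26, 3), 1) == "high"

    def test_non_monotone_grid_rejected(self):
        grid = default_matrix().grid
        bad = [row[:] for row in grid]
        bad[4][5] = "low"  # hole inside a medium band
        with pytest.raises(ValueError, match="monotone"):
            RiskMatrix(bad)

    def test_override_violation_rejected(self):
        bad = [["low"] * 10 for _ in range(10)]
        with pytest.raises(ValueError, match="override"):
            RiskMatrix(bad)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="10"):
            RiskMatrix([["low"] * 10] * 9)

    def test_file_roundtrip(self, matrix, tmp_path):
        path = tmp_path / "matrix.txt"
        matrix.to_file(path)
        assert RiskMatrix.from_file(path).grid == matrix.grid


def _mode(i, O=1, S=1, D=1, role="r"):
    return FailureMode(id=f"m{i}", role=role, O=Fraction(O), S=Fraction(S), D=Fraction(D))


class TestTopFraction:
    def test_distinct_rpns_top_two_of_ten(self):
        reg = Register(modes=[_mode(i, O=i + 1, S=1, D=1) for i in range(10)])
        top_fraction(reg, 0.2, key="rpn")
        flagged = {fm.id for fm in reg if fm.top_rpn_flag}
        assert flagged == {"m8", "m9"}

    def test_all_tied_means_all_flagged(self):
        reg = Register(modes=[_mode(i, O=3, S=3, D=3) for i in range(5)])
        top_fraction(reg, 0.2, key="rpn")
        assert all(fm.top_rpn_flag for fm in reg)

    def test_fraction_one_flags_everything(self, register):
        top_fraction(register, 1.0, key="rpn")
        assert all(fm.top_rpn_flag for fm in register)

    def test_severity_key_sets_other_flag(self):
        reg = Register(modes=[_mode(i, S=i + 1) for i in range(10)])
        top_fraction(reg, 0.2, key="severity")
        assert {fm.id for fm in reg if fm.top_severity_flag} == {"m8", "m9"}
        assert not any(fm.top_rpn_flag for fm in reg)

    def test_grouped_ranking_is_per_role(self):
        modes = [_mode(i, O=i + 1, role="a") for i in range(5)]
        modes += [_mode(i + 5, O=i + 1, role="b") for i in range(10)]
        reg = Register(modes=modes)
        top_fraction(reg, 0.2, key="rpn", group_by="role")
        by_role = {"a": set(), "b": set()}
        for fm in reg:
            if fm.top_rpn_flag:
                by_role[fm.role].add(fm.id)
        assert by_role["a"] == {"m4"}          # ceil(0.2 * 5) = 1
        assert by_role["b"] == {"m13", "m14"}  # ceil(0.2 * 10) = 2

    def test_flagged_set_contains_everything_above_cutoff(self, register):
        top_fraction(register, 0.2, key="rpn")
        cut = min(fm.rpn for fm in register if fm.top_rpn_flag)
        for fm in register:
            if fm.rpn > cut:
                assert fm.top_rpn_flag

    def test_removing_unflagged_mode_keeps_flags_stable(self, register):
        top_fraction(register, 0.2, key="rpn")
        flagged = {fm.id for fm in register if fm.top_rpn_flag}
        survivors = [fm for fm in register.modes if fm.top_rpn_flag or fm.id != "fm47"]
        smaller = Register(modes=[FailureMode(**{
            "id": fm.id, "role": fm.role, "O": fm.O, "S": fm.S, "D": fm.D,
        }) for fm in survivors])
        top_fraction(smaller, 0.2, key="rpn")
        assert {fm.id for fm in smaller if fm.top_rpn_flag} == flagged

    def test_invalid_fraction_rejected(self, register):
        with pytest.raises(ValueError):
            top_fraction(register, 0.0)
        with pytest.raises(ValueError):
            top_fraction(register, 1.5)


class TestSummarizeAndAudit:
    def test_empty_register_all_zero(self, matrix):
        counts = summarize(Register(), matrix)
        assert counts == {
            "total": 0, "high": 0, "medium": 0, "low": 0,
            "n_top_rpn": 0, "n_top_severity": 0,
        }

    def test_level_partition_sums_to_total(self, register, matrix):
        counts = summarize(register, matrix)
        assert counts["total"] == 47
        assert counts["high"] + counts["medium"] + counts["low"] == 47

    def test_audit_flags_rounding_inconsistent_rows(self):
        good = FailureMode(id="ok", O=Fraction(3), S=Fraction(23, 3), D=Fraction(3),
                           printed_rpn=69.0)
        bad = FailureMode(id="bad", O=Fraction(11, 3), S=Fraction(14, 3), D=Fraction(3),
                          printed_rpn=51.13)
        rows = audit_register(Register(modes=[good, bad]), tolerance_abs=0.1)
        assert [r.id for r in rows] == ["bad"]
        assert rows[0].recomputed_rpn == 51.33

    def test_infinite_tolerance_flags_nothing(self, register):
        assert audit_register(register, tolerance_abs=math.inf) == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Register(modes=[_mode(1), _mode(1)])


def test_display_round_is_half_away_from_zero():
    assert display_round(Fraction(5, 2), 0) == 3.0
    assert display_round(Fraction(-5, 2), 0) == -3.0
    assert display_round(Fraction(1209, 10000)) == 0.12
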