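"""Comparison systems: LLR values, corrections, pairing, tier ordering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_pairing import recursive_pick_the_best

from bayeslink.comparison import (
    NEG_INF,
    FourStateParams,
    InvalidComparisonParameter,
    MultiComparisonContext,
    ThreeStateParams,
    TwoStateParams,
    best_pairing_unordered,
    check_comparison_ordering,
    llr_three_state,
    llr_two_state,
    ordered_correction,
    unordered_correction,
)

# Printed worked-example parameters: male forename JAMES and surname ALLEN
# (ALLEN's error rates are the F/M-weighted means of the gendered defaults).
JAMES = FourStateParams(p_ep1=0.0084, p_ep2np1=0.00688, p_en=0.00625,
                        p_f=0.0295, p_p1nf=0.000133, p_p2np1=0.01)
ALLEN = FourStateParams(p_ep1=0.00510, p_ep2np1=0.00314, p_en=0.0355,
                        p_f=0.0028, p_p1nf=0.0002, p_p2np1=0.110)


class TestTwoState:
    def test_gender_match_at_defaults(self):
        # p_f = composed female prior 0.51 * (1 - 0.004)
        params = TwoStateParams(p_e=0.0033, p_f=0.50796)
        assert llr_two_state(True, params) == pytest.approx(
            math.log(0.9967 / 0.50796), abs=1e-9)
        assert llr_two_state(True, params) == pytest.approx(0.674, abs=0.001)

    def test_zero_error_mismatch_is_impossible_under_h(self):
        params = TwoStateParams(p_e=0.0, p_f=0.5)
        assert llr_two_state(False, params) == NEG_INF

    def test_uninformative_identifier_limit(self):
        # as p_f -> 1 with no errors, a match carries no information
        params = TwoStateParams(p_e=0.0, p_f=1 - 1e-12)
        assert llr_two_state(True, params) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_p_f_rejected(self):
        with pytest.raises(InvalidComparisonParameter):
            TwoStateParams(p_e=0.1, p_f=0.0)
        with pytest.raises(InvalidComparisonParameter):
            TwoStateParams(p_e=0.1, p_f=1.0)


class TestThreeState:
    def dob_params(self, b=30.0, p_ep=0.00459, p_en=0.0):
        from bayeslink import dob_probabilities
        p_f, p_pnf, _ = dob_probabilities(b)
        return ThreeStateParams(p_ep=p_ep, p_en=p_en, p_f=p_f, p_pnf=p_pnf)

    def test_exact_dob_match_adds_9_3(self):
        assert llr_three_state("full", self.dob_params()) == pytest.approx(9.3, abs=0.05)

    def test_complete_dob_mismatch_disallowed_at_defaults(self):
        assert llr_three_state("none", self.dob_params()) == NEG_INF

    def test_partial_dob_llr_closed_form(self):
        p_pnf = (16 * 30 + 631) / (5844 * 30)
        expected = math.log(0.00459 / p_pnf)
        assert llr_three_state("partial1", self.dob_params()) == pytest.approx(expected)
        assert expected == pytest.approx(-0.323, abs=0.001)

    def test_zero_partial_denominator_rejected(self):
        with pytest.raises(InvalidComparisonParameter):
            ThreeStateParams(p_ep=0.01, p_en=0.0, p_f=0.5, p_pnf=0.0)


class TestFourState:
    @pytest.mark.parametrize("params,tier,expected", [
        (JAMES, "partial1", 4.15),   # metaphone-not-full beats ...
        (JAMES, "full", 3.50),       # ... a full match for JAMES
        (ALLEN, "partial2", -3.56),  # F2C-only worse than ...
        (ALLEN, "none", -3.22),      # ... a complete mismatch for ALLEN
    ])
    def test_printed_worked_examples(self, params, tier, expected):
        assert params.llr(tier) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_denominator_with_positive_numerator_rejected(self):
        with pytest.raises(InvalidComparisonParameter):
            FourStateParams(p_ep1=0.01, p_ep2np1=0.0, p_en=0.0,
                            p_f=0.1, p_p1nf=0.0, p_p2np1=0.1)


@settings(derandomize=True, max_examples=200)
@given(p_ep1=st.floats(0.001, 0.3), p_ep2np1=st.floats(0.001, 0.3),
       p_en=st.floats(0.0, 0.3),
       p_f=st.floats(0.001, 0.3), p_p1nf=st.floats(0.001, 0.3),
       p_p2np1=st.floats(0.001, 0.3))
def test_columns_sum_to_one(p_ep1, p_ep2np1, p_en, p_f, p_p1nf, p_p2np1):
    """Both probability columns of every comparison system are conserved."""
    params = FourStateParams(p_ep1=p_ep1, p_ep2np1=p_ep2np1, p_en=p_en,
                             p_f=p_f, p_p1nf=p_p1nf, p_p2np1=p_p2np1)
    assert params.p_c + p_ep1 + p_ep2np1 + p_en == pytest.approx(1.0)
    assert p_f + p_p1nf + p_p2np1 + params.p_n == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100)
@given(p_e=st.floats(0.001, 0.5), p_f1=st.floats(0.01, 0.5),
       scale=st.floats(1.01, 1.9))
def test_llr_monotone_in_probabilities(p_e, p_f1, scale):
    """The LLR rises with P(D|H) and falls with P(D|¬H)."""
    lo = TwoStateParams(p_e=p_e, p_f=min(p_f1 * scale, 0.99))
    hi = TwoStateParams(p_e=p_e, p_f=p_f1)
    assert llr_two_state(True, hi) > llr_two_state(True, lo)
    smaller_error = TwoStateParams(p_e=p_e / scale, p_f=p_f1)
    assert llr_two_state(True, smaller_error) > llr_two_state(True, hi)


class TestCorrections:
    @pytest.mark.parametrize("c,m,expected", [
        (1, 1, 0.0),                 # single comparison: no correction
        (1, 2, -math.log(2)),        # pick-the-best of two candidates
        (2, 3, -math.log(6)),        # product 3*2
        (0, 5, 0.0),                 # pure non-matches need no correction
    ])
    def test_unordered_values(self, c, m, expected):
        assert unordered_correction(c, m) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(m=st.integers(1, 8), data=st.data())
    def test_unordered_never_positive(self, m, data):
        c = data.draw(st.integers(0, m))
        value = unordered_correction(c, m)
        assert value <= 0
        assert (value == 0) == (c == 0 or (c == 1 and m == 1))

    def test_bonferroni_is_conservative(self):
        """exp(correction) uses mq >= 1 - (1-q)^m, never undercorrecting."""
        for q in np.linspace(0.001, 0.999, 25):
            for m in range(1, 11):
                assert min(m * q, 1.0) >= 1 - (1 - q) ** m - 1e-12

    def test_ordered_strict_match(self):
        ctx = MultiComparisonContext(n=2, m=2, c=2, ordered=True,
                                     strict_order=True, p_o=1 - 0.00191)
        assert ordered_correction(ctx) == pytest.approx(math.log(0.99809))
        assert ordered_correction(ctx) == pytest.approx(-0.0019, abs=1e-4)

    def test_ordered_mismatch_c1_m2(self):
        ctx = MultiComparisonContext(n=1, m=2, c=1, ordered=True,
                                     strict_order=False, p_o=1 - 0.00191)
        assert ordered_correction(ctx) == pytest.approx(math.log(0.00191))

    def test_ordered_mismatch_c2_m2(self):
        # product 2*1 minus the one ordered arrangement leaves 1: no ¬H term
        ctx = MultiComparisonContext(n=2, m=2, c=2, ordered=True,
                                     strict_order=False, p_o=0.9)
        assert ordered_correction(ctx) == pytest.approx(math.log(0.1))

    def test_ordered_no_correction_for_single_possibility(self):
        ctx = MultiComparisonContext(n=1, m=1, c=1, ordered=True,
                                     strict_order=True, p_o=0.99)
        assert ordered_correction(ctx) == 0.0

    def test_ordered_degenerate_p_o_rejected(self):
        ctx = MultiComparisonContext(n=2, m=2, c=1, ordered=True,
                                     strict_order=False, p_o=1.0)
        with pytest.raises(InvalidComparisonParameter):
            ordered_correction(ctx)


class TestBestPairing:
    def test_single_pair(self):
        pairs, c = best_pairing_unordered([[2.0]])
        assert pairs == [(0, 0, 2.0)] and c == 1

    def test_diagonal_dominant_matches_optimal_assignment(self):
        pairs, c = best_pairing_unordered([[5.0, 1.0], [1.0, 4.0]])
        assert [(i, j) for i, j, _ in pairs] == [(0, 0), (1, 1)] and c == 2

    def test_no_positive_comparison(self):
        pairs, c = best_pairing_unordered([[-3.0, -3.0]])
        assert c == 0 and len(pairs) == 1
        # deterministic tie-break: lowest candidate index
        assert pairs[0][:2] == (0, 0)

    @settings(derandomize=True, max_examples=300)
    @given(n=st.integers(1, 4), m=st.integers(1, 4), data=st.data())
    def test_agrees_with_exhaustive_pick_the_best(self, n, m, data):
        matrix = [[data.draw(st.floats(-10, 10, allow_nan=False)) for _ in range(m)]
                  for _ in range(n)]
        assert best_pairing_unordered(matrix) == recursive_pick_the_best(matrix)

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(1, 4), m=st.integers(1, 4), data=st.data())
    def test_never_beats_optimal_assignment(self, n, m, data):
        from scipy.optimize import linear_sum_assignment
        matrix = np.array([[data.draw(st.floats(-10, 10, allow_nan=False))
                            for _ in range(m)] for _ in range(n)])
        pairs, _ = best_pairing_unordered(matrix.tolist())
        greedy_total = sum(llr for _, _, llr in pairs)
        rows, cols = linear_sum_assignment(-matrix)
        assert greedy_total <= matrix[rows, cols].sum() + 1e-9


class TestOrderingChecks:
    def test_james_partial_beats_full(self):
        warnings = check_comparison_ordering(JAMES, label="JAMES")
        assert any("partial1" in w and "full" in w for w in warnings)

    def test_allen_partial2_below_none(self):
        warnings = check_comparison_ordering(ALLEN, label="ALLEN")
        assert any("none" in w and "partial2" in w for w in warnings)

    def test_dob_defaults_are_well_ordered(self):
        from bayeslink import dob_probabilities
        p_f, p_pnf, _ = dob_probabilities(30.0)
        params = ThreeStateParams(p_ep=0.00459, p_en=0.0, p_f=p_f, p_pnf=p_pnf)
        assert check_comparison_ordering(params) == []
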