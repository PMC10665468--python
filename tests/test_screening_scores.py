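"""The seven laboratory screening scores, NLR grading, and their cutoffs.

Band boundaries are checked by an independent bisection oracle: given the
implemented classifier as a black box, bisect between two inputs with
different codes and confirm the switch point lands on the published cutoff
to 1e-9.
"""

import pytest
from hypothesis import given, settings, strategies as st

from malnut import (
    NlrGrade,
    VbdRefRanges,
    classify_ina,
    classify_vbd,
    compute_gnri,
    compute_idm,
    compute_lxa,
    compute_nlr,
    compute_pma,
    compute_pmac,
    grade_nlr,
)
from malnut.screening_scores import code_gnri, code_lxa, code_pma


def bisect_boundary(classify, lo, hi, tol=1e-12):
    """Locate where a 1-D classifier switches code, to within ``tol``."""
    assert classify(lo) != classify(hi)
    code_lo = classify(lo)
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if classify(mid) == code_lo:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return hi


class TestNlr:
    def test_quotient(self):
        assert compute_nlr(4000, 2000) == pytest.approx(2.0)
        assert compute_nlr(6000, 1000) == pytest.approx(6.0)

    def test_zero_lymphocytes_guarded(self):
        with pytest.raises(ValueError):
            compute_nlr(1000, 0)

    @pytest.mark.parametrize(
        "nlr, grade",
        [
            (1.99, NlrGrade.NORMAL),
            (2.0, NlrGrade.LOW),
            (3.99, NlrGrade.LOW),
            (4.0, NlrGrade.MILD),
            (5.5, NlrGrade.MILD),
            (6.0, NlrGrade.MODERATE),
            (7.99, NlrGrade.MODERATE),
            (8.0, NlrGrade.SEVERE),
        ],
    )
    def test_inflammation_grades(self, nlr, grade):
        assert grade_nlr(nlr) is grade

    @pytest.mark.parametrize("cutoff", [2.0, 4.0, 6.0, 8.0])
    def test_grade_boundaries_by_bisection(self, cutoff):
        found = bisect_boundary(grade_nlr, cutoff - 1.0, cutoff + 1.0)
        assert found == pytest.approx(cutoff, abs=1e-9)


class TestGnri:
    def test_weight_term_coefficient(self):
        """With no albumin and ABW = IBW only the 41.7 weight term remains."""
        assert compute_gnri(0.0, 70.0, 70.0).value == pytest.approx(41.7)

    def test_hand_arithmetic_no_risk(self):
        res = compute_gnri(40.0, 70.0, 70.0)
        assert res.value == pytest.approx(1.489 * 40 + 41.7)
        assert res.code == 0

    def test_hand_arithmetic_major_risk(self):
        res = compute_gnri(27.0, 70.0, 70.0)
        assert res.value == pytest.approx(81.903)
        assert res.code == 3

    def test_ratio_cap_on_by_default(self):
        capped = compute_gnri(35.0, 90.0, 70.0)
        assert capped.value == pytest.approx(1.489 * 35 + 41.7)
        uncapped = compute_gnri(35.0, 90.0, 70.0, cap_ratio=False)
        assert uncapped.value == pytest.approx(1.489 * 35 + 41.7 * 90 / 70)

    @pytest.mark.parametrize("cutoff", [82.0, 92.0, 98.0])
    def test_risk_band_boundaries_by_bisection(self, cutoff):
        found = bisect_boundary(code_gnri, cutoff - 1.0, cutoff + 1.0)
        assert found == pytest.approx(cutoff, abs=1e-9)

    def test_missing_albumin_not_applicable(self):
        res = compute_gnri(None, 70.0, 70.0)
        assert not res.applicable and "ALB" in res.reason

    @given(
        alb_lo=st.floats(min_value=0, max_value=50),
        delta=st.floats(min_value=1e-6, max_value=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_albumin(self, alb_lo, delta):
        v1 = compute_gnri(alb_lo, 70.0, 70.0).value
        v2 = compute_gnri(alb_lo + delta, 70.0, 70.0).value
        assert v2 > v1


class TestIna:
    @pytest.mark.parametrize(
        "alb_gl, lymc, code",
        [
            (35.0, 1500.0, 0),   # both at boundary: no risk (inclusive)
            (34.0, 1600.0, 1),   # low albumin only: protein risk
            (36.0, 1200.0, 2),   # low lymphocytes only: energy risk
            (34.0, 1400.0, 3),   # both low: protein-energy risk
        ],
    )
    def test_quadrants(self, alb_gl, lymc, code):
        assert classify_ina(alb_gl, lymc).code == code

    def test_missing_inputs_not_applicable(self):
        res = classify_ina(None, 1500.0)
        assert not res.applicable and "ALB" in res.reason

    def test_albumin_boundary_by_bisection(self):
        # vary albumin (g/L) at healthy lymphocytes; switch at 3.5 g/dL
        found = bisect_boundary(lambda a: classify_ina(a, 2000.0).code, 30.0, 40.0)
        assert found == pytest.approx(35.0, abs=1e-9)

    def test_lymphocyte_boundary_by_bisection(self):
        found = bisect_boundary(lambda l: classify_ina(40.0, l).code, 1000.0, 2000.0)
        assert found == pytest.approx(1500.0, abs=1e-6)


class TestLxa:
    def test_poor_boundary_product(self):
        res = compute_lxa(903.0, 50.0)  # 903 cells/uL x 5.0 g/dL = 4515
        assert res.value == pytest.approx(4515.0)
        assert res.code == 2

    def test_middle_band(self):
        res = compute_lxa(1500.0, 35.0)
        assert res.value == pytest.approx(5250.0)
        assert res.code == 1

    def test_good_nutrition(self):
        res = compute_lxa(2000.0, 45.0)
        assert res.value == pytest.approx(9000.0)
        assert res.code == 0

    @pytest.mark.parametrize("cutoff", [4515.0, 7920.0])
    def test_band_boundaries_by_bisection(self, cutoff):
        found = bisect_boundary(code_lxa, cutoff - 100.0, cutoff + 100.0)
        assert found == pytest.approx(cutoff, abs=1e-9)

    @given(
        lymc=st.floats(min_value=100, max_value=5000),
        alb=st.floats(min_value=10, max_value=55),
        bump=st.floats(min_value=1.0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_each_factor(self, lymc, alb, bump):
        base = compute_lxa(lymc, alb).value
        assert compute_lxa(lymc + bump, alb).value > base
        assert compute_lxa(lymc, alb + bump).value > base


class TestPma:
    def test_zero_crp(self):
        res = compute_pma(0.0, 40.0)
        assert res.value == 0.0 and res.code == 0

    def test_high_risk(self):
        res = compute_pma(10.0, 40.0)
        assert res.value == pytest.approx(2.5) and res.code == 3

    def test_moderate_band_left_closed(self):
        res = compute_pma(4.8, 40.0)
        assert res.value == pytest.approx(1.2) and res.code == 2

    def test_zero_albumin_not_applicable(self):
        assert not compute_pma(5.0, 0.0).applicable

    @pytest.mark.parametrize("cutoff", [0.4, 1.2, 2.0])
    def test_band_boundaries_by_bisection(self, cutoff):
        found = bisect_boundary(code_pma, cutoff - 0.2, cutoff + 0.2)
        assert found == pytest.approx(cutoff, abs=1e-9)

    @given(
        crp=st.floats(min_value=0.01, max_value=200),
        alb=st.floats(min_value=20, max_value=55),
        bump=st.floats(min_value=0.1, max_value=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_crp_and_albumin(self, crp, alb, bump):
        base = compute_pma(crp, alb).value
        assert compute_pma(crp + bump, alb).value > base
        assert compute_pma(crp, alb + bump).value < base


class TestPmac:
    def test_hand_arithmetic(self):
        # (2 + 5) / (4.0 g/dL + 200 mg/L) with albumin given canonically (40 g/L)
        res = compute_pmac(2.0, 5.0, 40.0, 200.0)
        assert res.value == pytest.approx(7.0 / 204.0)

    def test_zero_numerator(self):
        assert compute_pmac(0.0, 0.0, 40.0, 200.0).value == 0.0

    def test_missing_component_not_applicable(self):
        res = compute_pmac(2.0, 5.0, None, 200.0)
        assert not res.applicable
        assert res.reason == "missing CRP, NLR, ALB, or PALB"

    def test_code_is_provisional_until_cohort_coding(self):
        assert compute_pmac(2.0, 5.0, 40.0, 200.0).code == -1


class TestIdm:
    def test_constant_when_hemoglobin_at_target(self):
        """IHB = AHB leaves only the 500 mg constant, at any weight."""
        for abw in (40.0, 70.0, 120.0):
            assert compute_idm(abw, 150.0, 150.0).value == 500.0

    def test_hand_arithmetic_ganzoni(self):
        # 70 kg x (15 - 10) g/dL x 2.4 + 500
        assert compute_idm(70.0, 150.0, 100.0).value == pytest.approx(1340.0)

    def test_hemoglobin_above_target_not_applicable(self):
        res = compute_idm(70.0, 100.0, 150.0)
        assert not res.applicable
        assert res.reason == "IHB lower than AHB"

    @given(
        abw=st.floats(min_value=30, max_value=200),
        deficit=st.floats(min_value=0, max_value=80),
        bump=st.floats(min_value=0.5, max_value=30),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_weight_and_deficit(self, abw, deficit, bump):
        base = compute_idm(abw, 150.0, 150.0 - deficit).value
        assert compute_idm(abw + bump, 150.0, 150.0 - deficit).value >= base
        assert compute_idm(abw, 150.0 + bump, 150.0 - deficit).value > base


class TestVbd:
    def test_macrocytic_hyperchromic_flags(self):
        assert classify_vbd(105.0, 36.0, 33.0).code == 1

    def test_all_in_range_clear(self):
        assert classify_vbd(90.0, 30.0, 33.0).code == 0

    def test_macrocytosis_alone_insufficient(self):
        assert classify_vbd(105.0, 30.0, 33.0).code == 0

    def test_low_mchc_with_macrocytosis_flags(self):
        assert classify_vbd(105.0, 30.0, 31.0).code == 1

    def test_alternative_precedence_variant(self):
        # (MCV up AND MCH up) OR MCHC down: low MCHC alone is enough
        res = classify_vbd(90.0, 30.0, 31.0, macrocytosis_required=False)
        assert res.code == 1

    def test_missing_index_not_applicable(self):
        res = classify_vbd(None, 30.0, 33.0)
        assert not res.applicable and "MCV" in res.reason

    def test_custom_reference_ranges(self):
        refs = VbdRefRanges(mcv_high=95.0, mch_high=32.0, mchc_low=33.0)
        assert classify_vbd(96.0, 33.0, 34.0, refs).code == 1


class TestPartitionProperty:
    """Every banded classifier assigns exactly one code to any input."""

    @given(st.floats(min_value=0, max_value=500, allow_nan=False))
    @settings(max_examples=500, deadline=None)
    def test_gnri_bands_total(self, value):
        assert code_gnri(value) in (0, 1, 2, 3)

    @given(st.floats(min_value=0, max_value=30000, allow_nan=False))
    @settings(max_examples=500, deadline=None)
    def test_lxa_bands_total(self, value):
        assert code_lxa(value) in (0, 1, 2)

    @given(st.floats(min_value=0, max_value=50, allow_nan=False))
    @settings(max_examples=500, deadline=None)
    def test_pma_bands_total(self, value):
        assert code_pma(value) in (0, 1, 2, 3)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=500, deadline=None)
    def test_nlr_grades_total(self, value):
        assert grade_nlr(value) in NlrGrade
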