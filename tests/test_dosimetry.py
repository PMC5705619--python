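import pytest
from hypothesis import given, settings, strategies as st

from terradose import (
    ActivityRecord,
    absorbed_dose_rate,
    annual_effective_dose,
    contribution_percentages,
    dose_table,
)

SS1 = ActivityRecord("SS1", 8.96, 9.12, 298.0, 1.5, 1.2, 44.7)

conc = st.floats(0.0, 1e4)
record = st.builds(
    ActivityRecord,
    st.just("H"),
    conc, conc, conc,
    st.floats(0.0, 100.0), st.floats(0.0, 100.0), st.floats(0.0, 100.0),
)


class TestAbsorbedDose:
    def test_published_anchor_sample(self, coeff):
        d, sd = absorbed_dose_rate(SS1, coeff)
        assert d == pytest.approx(22.0746, abs=1e-4)
        assert sd == pytest.approx(3.28, abs=0.005)

    def test_all_zero_record(self, coeff):
        assert absorbed_dose_rate(ActivityRecord("Z", 0, 0, 0), coeff) == (0.0, 0.0)

    def test_quadrature_mode_differs(self, coeff):
        _, lin = absorbed_dose_rate(SS1, coeff, "linear")
        _, quad = absorbed_dose_rate(SS1, coeff, "quadrature")
        assert lin == pytest.approx(3.28, abs=0.005)
        assert quad == pytest.approx(2.12, abs=0.005)
        assert quad < lin

    @given(a=record, b=record)
    @settings(max_examples=50, derandomize=True)
    def test_linearity_in_records(self, a, b, coeff):
        summed = ActivityRecord(
            "S", a.c_u + b.c_u, a.c_th + b.c_th, a.c_k + b.c_k
        )
        da, _ = absorbed_dose_rate(a, coeff)
        db, _ = absorbed_dose_rate(b, coeff)
        ds, _ = absorbed_dose_rate(summed, coeff)
        assert ds == pytest.approx(da + db, rel=1e-9, abs=1e-9)


class TestEffectiveDose:
    def test_unit_dose_rate_factor(self, coeff):
        e, _ = annual_effective_dose(1.0, 0.0, coeff)
        assert e == pytest.approx(1.22724)

    def test_anchor_sample(self, coeff):
        d, sd = absorbed_dose_rate(SS1, coeff)
        e, se = annual_effective_dose(d, sd, coeff)
        assert e == pytest.approx(27.1, abs=0.05)
        assert se == pytest.approx(4.0, abs=0.05)

    def test_zero_dose(self, coeff):
        assert annual_effective_dose(0.0, 0.0, coeff) == (0.0, 0.0)

    def test_negative_dose_rejected(self, coeff):
        with pytest.raises(ValueError):
            annual_effective_dose(-1.0, 0.0, coeff)

    @given(d=st.floats(0.001, 1e3))
    @settings(max_examples=30, derandomize=True)
    def test_ratio_constant_across_doses(self, d, coeff):
        e, _ = annual_effective_dose(d, 0.0, coeff)
        assert e / d == pytest.approx(coeff.dose_to_effective)


class TestContributions:
    def test_anchor_sample(self, coeff):
        pu, pth, pk = contribution_percentages(SS1, coeff)
        assert (pu, pth, pk) == (
            pytest.approx(18.7, rel=0.005),
            pytest.approx(24.9, rel=0.005),
            pytest.approx(56.3, rel=0.005),
        )

    def test_single_nuclide_record(self, coeff):
        pu, pth, pk = contribution_percentages(
            ActivityRecord("U", 5.0, 0.0, 0.0), coeff
        )
        assert (pu, pth, pk) == (100.0, 0.0, 0.0)

    def test_thorium_share_of_potassium_rich_sample(self, coeff):
        # the survey's Th-minimum sample; its printed cell is a known typo
        rec = ActivityRecord("SS23", 5.59, 2.78, 528.0)
        _, pth, _ = contribution_percentages(rec, coeff)
        assert pth == pytest.approx(6.39, abs=0.005)

    def test_zero_dose_undefined(self, coeff):
        with pytest.raises(ValueError):
            contribution_percentages(ActivityRecord("Z", 0, 0, 0), coeff)

    @given(r=record)
    @settings(max_examples=50, derandomize=True)
    def test_contributions_sum_to_100(self, r, coeff):
        d, _ = absorbed_dose_rate(r, coeff)
        if d == 0:
            return
        assert sum(contribution_percentages(r, coeff)) == pytest.approx(100.0, abs=0.1)


class TestDoseTable:
    def test_survey_summary(self, survey, coeff):
        _, summary = dose_table(survey, coeff)
        assert summary.loc["mean", "absorbed_dose_ngy_h"] == pytest.approx(20.5, abs=0.05)
        assert summary.loc["mean", "effective_dose_usv_y"] == pytest.approx(25.1, abs=0.05)

    def test_survey_extremes(self, survey, coeff):
        results, summary = dose_table(survey, coeff)
        by_id = {r.sample_id: r for r in results}
        assert summary.loc["max", "absorbed_dose_ngy_h"] == by_id["SS15"].absorbed_dose
        assert by_id["SS15"].absorbed_dose == pytest.approx(37.8, abs=0.05)
        assert summary.loc["min", "effective_dose_usv_y"] == by_id["SS6"].effective_dose
        assert by_id["SS6"].effective_dose == pytest.approx(9.56, abs=0.02)

    def test_empty_rejected(self, coeff):
        with pytest.raises(ValueError):
            dose_table([], coeff)
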