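"""Base case, uptake scenarios, sensitivity analyses and annualization."""

import pytest
from hypothesis import given, strategies as st

from flscost import (
    CohortSpec,
    ConfigError,
    FLSCostModel,
    ScenarioSpec,
    adherence_sensitivity,
    annualize,
    nonresponder_leakage,
    percent_change_on_base,
    uptake_scenario,
)
from flscost.params import Stage


class TestBaseCase:
    def test_stage_costs_per_1000(self, base):
        got = {st.value: v for st, v in base.fls_stage_per_1000.items()}
        assert got["ed_record_assessment"] == pytest.approx(38_143, abs=0.01)
        assert got["patient_gp_contact"] == pytest.approx(42_732, abs=0.01)
        assert got["clinic_exam_treatment"] == pytest.approx(239_860, abs=0.01)
        assert got["followup_calls"] == pytest.approx(23_018, abs=0.01)
        assert base.fls_pathway_per_1000 == pytest.approx(343_753, abs=0.01)

    def test_totals_and_saving(self, base):
        assert base.fls_total == pytest.approx(2_804_378, abs=2)
        assert base.usual_total == pytest.approx(3_421_653, abs=2)
        assert base.net_saving == pytest.approx(617_275, abs=2)

    def test_usual_care_carries_refracture_cost_only(self, base):
        assert base.usual_pathway_per_1000 == 0.0
        assert base.usual_total == base.usual_refracture_per_1000

    def test_zero_stage_costs_and_equal_refractures_give_zero_saving(self, params):
        """Symmetry: identical refracture burdens and no pathway spend."""
        same = CohortSpec("FLS", 500, 0, {"hip": 10})
        other = CohortSpec("UsualCare", 500, 0, {"hip": 10})
        stages = {
            st: sc.__class__(stage=st, labor_hours=0.0, wage_rate=0.0)
            for st, sc in params.stages.items()
        }
        p = params.replace(fls=same, usual=other, stages=stages)
        assert FLSCostModel(p).fit().net_saving == pytest.approx(0.0, abs=1e-9)

    def test_swapping_cohort_profiles_negates_saving(self, params):
        """Antisymmetry of the net saving in the two cohorts' cost profiles."""
        a = CohortSpec("FLS", 500, 0, {"hip": 5, "wrist": 20})
        b = CohortSpec("UsualCare", 500, 0, {"hip": 15, "wrist": 2})
        stages = {
            st: sc.__class__(stage=st, labor_hours=0.0, wage_rate=0.0)
            for st, sc in params.stages.items()
        }
        fwd = FLSCostModel(params.replace(fls=a, usual=b, stages=stages)).fit()
        rev = FLSCostModel(
            params.replace(
                fls=CohortSpec("FLS", 500, 0, dict(b.n_refractures_by_category)),
                usual=CohortSpec("UsualCare", 500, 0,
                                 dict(a.n_refractures_by_category)),
                stages=stages,
            )
        ).fit()
        assert fwd.net_saving == pytest.approx(-rev.net_saving)


class TestUptakeScenarios:
    @pytest.mark.parametrize(
        "uptake, addon, saving",
        [
            (0.05, 65_720, 682_995),
            (0.10, 131_439, 748_715),
            (0.20, 262_878, 880_154),
        ],
    )
    def test_printed_scenarios(self, params, uptake, addon, saving):
        r = uptake_scenario(params, uptake)
        assert r.usual_pathway_per_1000 == pytest.approx(addon, abs=2)
        assert r.net_saving == pytest.approx(saving, abs=2)

    def test_zero_uptake_equals_base(self, model, base):
        r = model.fit(ScenarioSpec(usual_care_uptake=0.0))
        assert r.net_saving == base.net_saving
        assert r.usual_pathway_per_1000 == 0.0

    def test_uptake_at_attendance_rate_mirrors_fls_clinic_costs(self, model, base):
        """At 20% uptake the usual-care add-on equals the FLS arm's clinic +
        follow-up per-1000 costs exactly."""
        r = model.fit(ScenarioSpec(usual_care_uptake=0.20))
        clinic = base.fls_stage_per_1000[Stage.CLINIC_EXAM_TREATMENT]
        follow = base.fls_stage_per_1000[Stage.FOLLOWUP_CALLS]
        assert r.usual_stage_per_1000[Stage.CLINIC_EXAM_TREATMENT] == pytest.approx(clinic)
        assert r.usual_stage_per_1000[Stage.FOLLOWUP_CALLS] == pytest.approx(follow)
        # record-assessment and contact stay zero for usual care
        assert r.usual_stage_per_1000[Stage.ED_RECORD_ASSESSMENT] == 0.0
        assert r.usual_stage_per_1000[Stage.PATIENT_GP_CONTACT] == 0.0

    @given(u=st.floats(0.0, 1.0))
    def test_saving_non_decreasing_in_uptake(self, model, base, u):
        assert model.fit(ScenarioSpec(usual_care_uptake=u)).net_saving >= (
            base.net_saving - 1e-6
        )

    def test_uptake_above_one_rejected(self, model):
        with pytest.raises(ConfigError):
            model.fit(ScenarioSpec(usual_care_uptake=1.2))


class TestSensitivity:
    def test_adherence_identity_at_scale_one(self, params, base):
        assert adherence_sensitivity(params, 1.0) == pytest.approx(base.net_saving)

    @pytest.mark.parametrize(
        "scale, saving", [(1.15, 603_356), (1.25, 594_077), (1.35, 584_797)]
    )
    def test_adherence_scaling_matches_reported_savings(self, params, scale, saving):
        # higher adherence -> more medication spend -> smaller saving
        assert adherence_sensitivity(params, scale) == pytest.approx(
            saving, rel=1e-3
        )

    def test_nonresponder_zero_fraction_is_base(self, params, base):
        assert nonresponder_leakage(params, 0.0) == pytest.approx(base.net_saving)

    @pytest.mark.parametrize(
        "fraction, saving", [(0.10, 502_970), (0.20, 388_664), (0.30, 274_358)]
    )
    def test_nonresponder_savings_with_calibrated_cost(self, params, fraction, saving):
        assert nonresponder_leakage(params, fraction) == pytest.approx(
            saving, rel=2e-5
        )

    def test_nonresponder_deduction_is_linear(self, params, base):
        d1 = base.net_saving - nonresponder_leakage(params, 0.1, 1500.0)
        d2 = base.net_saving - nonresponder_leakage(params, 0.2, 1500.0)
        assert d2 == pytest.approx(2 * d1)
        # and the deduction equals fraction x non-responders/1000 x cost
        per_1000_nonresp = (515 - 103) / 515 * 1000
        assert d1 == pytest.approx(0.1 * per_1000_nonresp * 1500.0)


class TestDerived:
    @pytest.mark.parametrize(
        "scenario, base_s, expected",
        [(880_154.0, 617_275.0, 0.426), (748_715.0, 617_275.0, 0.213)],
    )
    def test_percent_change_on_base(self, scenario, base_s, expected):
        assert percent_change_on_base(scenario, base_s) == pytest.approx(
            expected, abs=5e-4
        )

    def test_percent_change_zero_base_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change_on_base(1.0, 0.0)

    @pytest.mark.parametrize(
        "saving, n, expected",
        [(880_154.0, 2000, 1_760_308.0), (42.0, 1000, 42.0), (42.0, 0, 0.0)],
    )
    def test_annualize(self, saving, n, expected):
        assert annualize(saving, n) == pytest.approx(expected)


def test_table_column_identity_every_scenario(model, base):
    """Net-cost column = FLS column - usual-care column, row-wise, in every
    scenario table."""
    for u in (0.0, 0.05, 0.10, 0.20):
        res = model.fit(ScenarioSpec(usual_care_uptake=u))
        df = res.to_frame()
        assert (
            (df["fls"] - df["usual_care"] - df["fls_net_cost"]).abs() < 1e-9
        ).all()


def test_results_to_dict_is_json_ready(base):
    import json

    payload = json.dumps(base.to_dict())
    assert "net_saving" in payload
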