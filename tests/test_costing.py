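"""Stage costing, normalisation, adherence and medication machinery."""

import pytest
from hypothesis import given, strategies as st

from flscost.costing import (
    full_adherence_equivalents,
    inflate,
    mean_adherence_fraction,
    medication_cost,
    per_thousand,
    stage_breakdown,
    stage_total,
    weighted_drug_cost,
)
from flscost.params import (
    AdherenceSchedule,
    DrugTherapy,
    FeeItem,
    PriceIndexSeries,
    Stage,
    StageCost,
)

frac = st.floats(0.0, 1.0)


# ---------------------------------------------------------------------------
# stage_total
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        # $100 labor at 27.5% overhead, nothing else
        (dict(labor_hours=2.0, wage_rate=50.0), 127.50),
        (dict(labor_hours=0.0, wage_rate=0.0), 0.0),
        # all components together
        (
            dict(
                labor_hours=10.0,
                wage_rate=40.0,
                consumables=25.0,
                fee_items=(FeeItem("consult", 100.0, 3),),
                medication=60.0,
            ),
            10 * 40 * 1.275 + 25 + 300 + 60,
        ),
    ],
)
def test_stage_total_components(kwargs, expected):
    s = StageCost(stage=Stage.CLINIC_EXAM_TREATMENT, **kwargs)
    assert stage_total(s) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# per_thousand
# ---------------------------------------------------------------------------


def test_per_thousand_matches_printed_record_assessment_stage():
    # oracle: inverse of the printed per-1000 figure, 38,143 * 515 / 1000
    whole_cohort = 38_143.0 * 515 / 1000.0
    assert per_thousand(whole_cohort, 515) == pytest.approx(38_143.0)


@pytest.mark.parametrize("total, n, expected", [(0.0, 416, 0.0), (777.0, 1000, 777.0)])
def test_per_thousand_trivial_cases(total, n, expected):
    assert per_thousand(total, n) == expected


def test_per_thousand_rejects_empty_cohort():
    with pytest.raises(ValueError):
        per_thousand(100.0, 0)


@given(
    c=st.floats(0, 1e7, allow_nan=False),
    k=st.floats(0, 100, allow_nan=False),
    n=st.integers(1, 10_000),
)
def test_per_thousand_linear_in_cost(c, k, n):
    assert per_thousand(k * c, n) == pytest.approx(k * per_thousand(c, n), abs=1e-6)


# ---------------------------------------------------------------------------
# weighted drug cost
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "drugs, expected",
    [
        ([("a", 1000.0, 0.5), ("b", 2000.0, 0.5)], 1500.0),
        ([("weighted", 1416.0, 1.0)], 1416.0),
        ([("a", 1000.0, 0.8), ("b", 3000.0, 0.2)], 1400.0),
    ],
)
def test_weighted_drug_cost(drugs, expected):
    formulary = [DrugTherapy(*d) for d in drugs]
    assert weighted_drug_cost(formulary) == pytest.approx(expected)


def test_weighted_drug_cost_rejects_bad_weights():
    with pytest.raises(ValueError, match="sum"):
        weighted_drug_cost([DrugTherapy("a", 1000.0, 0.7)])


# ---------------------------------------------------------------------------
# adherence
# ---------------------------------------------------------------------------


def test_default_schedule_mean_is_mid_year_average():
    """1.0 -> 0.50/0.35/0.25 gives year means 0.75/0.425/0.30, mean 0.49167."""
    a = AdherenceSchedule()
    assert a.year_means() == pytest.approx((0.75, 0.425, 0.30))
    assert mean_adherence_fraction(a) == pytest.approx(0.4916667, abs=1e-6)


def test_single_year_schedule():
    assert mean_adherence_fraction(
        AdherenceSchedule(year_end_fractions=(0.5,))
    ) == pytest.approx(0.75)


@given(c=frac, years=st.integers(1, 6))
def test_constant_schedule_mean_is_the_constant(c, years):
    a = AdherenceSchedule(year_end_fractions=(c,) * years, initial=c)
    assert mean_adherence_fraction(a) == pytest.approx(c)


def test_full_adherence_equivalents_reproduce_attendee_share():
    """103 attendees at 66.66% prescription and the default schedule come to
    ~34 fully adherent treated patients, ~33% of attendees."""
    mean = mean_adherence_fraction(AdherenceSchedule())
    fae = full_adherence_equivalents(103, 0.6666, mean)
    assert fae == pytest.approx(33.7577, abs=1e-3)
    assert round(fae) == 34
    assert fae / 103 == pytest.approx(0.33, abs=0.005)


def test_full_adherence_equivalents_zero_attendees():
    assert full_adherence_equivalents(0, 0.5, 0.5) == 0.0


# ---------------------------------------------------------------------------
# medication cost
# ---------------------------------------------------------------------------


def test_medication_cost_base_value():
    # oracle: direct product 33.757735 * 1416
    got = medication_cost(103, 0.6666, AdherenceSchedule(), 1416.0)
    assert got == pytest.approx(103 * 0.6666 * (0.75 + 0.425 + 0.30) / 3 * 1416.0)
    assert got == pytest.approx(47_800.95, abs=0.01)


def test_medication_cost_zero_prescription_rate():
    assert medication_cost(103, 0.0, AdherenceSchedule(), 1416.0) == 0.0


def test_medication_cost_linear_in_adherence_scale():
    base = medication_cost(103, 0.6666, AdherenceSchedule(), 1416.0)
    scaled = medication_cost(103, 0.6666, AdherenceSchedule(), 1416.0,
                             adherence_scale=1.15)
    assert scaled == pytest.approx(1.15 * base)


@given(
    n=st.integers(0, 500), rx=frac, cost=st.floats(0, 5000, allow_nan=False),
    f1=frac, f2=frac, f3=frac,
)
def test_medication_cost_monotone_in_each_argument(n, rx, cost, f1, f2, f3):
    fs = sorted([f1, f2, f3], reverse=True)
    a = AdherenceSchedule(year_end_fractions=tuple(fs))
    ref = medication_cost(n, rx, a, cost)
    assert medication_cost(n + 10, rx, a, cost) >= ref - 1e-9
    assert medication_cost(n, rx, a, cost + 100) >= ref - 1e-9
    higher = AdherenceSchedule(year_end_fractions=tuple(min(1.0, f + 0.1) for f in fs))
    assert medication_cost(n, rx, higher, cost) >= ref - 1e-9


# ---------------------------------------------------------------------------
# inflation
# ---------------------------------------------------------------------------

IDX = PriceIndexSeries("test", {2014: 100.0, 2015: 110.0, 2016: 121.0})


def test_inflate_same_year_identity():
    assert inflate(500.0, 2015, 2015, IDX) == 500.0


def test_inflate_ratio():
    assert inflate(500.0, 2014, 2015, IDX) == pytest.approx(550.0)


def test_inflate_chained_equals_direct():
    via = inflate(inflate(500.0, 2014, 2015, IDX), 2015, 2016, IDX)
    assert via == pytest.approx(inflate(500.0, 2014, 2016, IDX))


def test_inflate_missing_year():
    with pytest.raises(KeyError):
        inflate(500.0, 2010, 2015, IDX)


# ---------------------------------------------------------------------------
# breakdown export
# ---------------------------------------------------------------------------


def test_stage_breakdown_totals_match_stage_costs(params, base):
    df = stage_breakdown(params, base.stage_costs)
    assert set(df.columns) == {
        "stage", "component", "whole_cohort_AUD", "per_patient_AUD", "per_1000_AUD"
    }
    totals = df[df.component == "stage_total"].set_index("stage")["per_1000_AUD"]
    assert totals["ed_record_assessment"] == pytest.approx(38_143.0)
    assert totals["clinic_exam_treatment"] == pytest.approx(239_860.0)
    # component rows sum to the stage total within float tolerance
    for st_name, grp in df.groupby("stage"):
        parts = grp[grp.component != "stage_total"]["whole_cohort_AUD"].sum()
        tot = grp[grp.component == "stage_total"]["whole_cohort_AUD"].iloc[0]
        assert parts == pytest.approx(tot)
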