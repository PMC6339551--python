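"""Cost-comparison model: FLS versus usual care, base case and scenarios.

The public surface follows the model/results idiom: :class:`FLSCostModel`
is built from a validated parameter set (or from patient-level cohort data),
``fit()`` evaluates the deterministic cost model and returns
:class:`FLSCostResults` carrying the per-1000 cost table, the net saving,
the incidence comparison, and rendering/scenario helpers.

Accounting rules
----------------
* The FLS arm carries four pathway stage costs plus its refracture
  treatment cost; the usual-care arm carries refracture cost only (base
  case assumption: no preventative care without an FLS).
* Record-assessment and contact stages cost over the whole FLS cohort;
  clinic and follow-up stages accrue only for attendees.  Every per-1000
  figure is normalised over the full cohort, non-attendees included.
* Uptake scenarios grant a fraction ``u`` of the usual-care cohort
  FLS-grade clinic + follow-up care at the FLS per-attendee cost, i.e. an
  add-on of ``u / attendance_rate`` times the FLS per-1000 clinic and
  follow-up costs; record-assessment and contact stay zero (no FLS
  infrastructure exists in that arm).  Refracture counts are unchanged.
* Net saving = usual-care total - FLS total (positive favours the FLS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import costing, refracture
from .incidence import IncidenceResult, compare_incidence
from .params import (
    ATTENDEE_STAGES,
    Parameters,
    ScenarioSpec,
    Stage,
    StageCost,
    default_parameters,
    load_config,
)

__all__ = [
    "FLSCostModel",
    "FLSCostResults",
    "base_case",
    "uptake_scenario",
    "adherence_sensitivity",
    "nonresponder_leakage",
    "percent_change_on_base",
    "annualize",
]

_STAGE_LABELS = {
    Stage.ED_RECORD_ASSESSMENT: "FLS assessment of ED records",
    Stage.PATIENT_GP_CONTACT: "FLS contact with patients/GPs",
    Stage.CLINIC_EXAM_TREATMENT: "FLS examination/treatment",
    Stage.FOLLOWUP_CALLS: "FLS Follow up",
}


class FLSCostModel:
    """Micro-costing comparison of an FLS cohort against usual care.

    Parameters
    ----------
    params : Parameters, optional
        Validated parameter set; the calibrated base case when omitted.
    """

    def __init__(self, params: Parameters | None = None):
        self.params = (params if params is not None else default_parameters()).validate()

    @classmethod
    def from_config(cls, path: str | Path) -> "FLSCostModel":
        """Build a model from a JSON/YAML configuration file."""
        return cls(load_config(path))

    @classmethod
    def from_cohorts(
        cls,
        fls_records: pd.DataFrame,
        usual_records: pd.DataFrame,
        params: Parameters | None = None,
    ) -> "FLSCostModel":
        """Build a model from patient-level cohort tables.

        Cohort sizes, attendee counts and refracture tallies are taken from
        the records (see :func:`flscost.simulate.tabulate`); all cost
        parameters come from ``params`` (default base case).
        """
        from .simulate import tabulate

        base = params if params is not None else default_parameters()
        fls_spec, _ = tabulate(fls_records)
        usual_spec, _ = tabulate(usual_records)
        return cls(base.replace(fls=fls_spec, usual=usual_spec))

    # ------------------------------------------------------------------
    def fit(self, scenario: ScenarioSpec | None = None) -> "FLSCostResults":
        """Evaluate the cost model and return results.

        ``scenario`` applies usual-care uptake, adherence scaling and/or
        non-responder leakage on top of the base case; ``None`` is the base
        case.
        """
        sc = scenario or ScenarioSpec()
        errs = sc.invariant_errors()
        if errs:
            from .params import ConfigError

            raise ConfigError(errs)
        p = self.params
        fls, usual = p.fls, p.usual

        # medication: prescription-weighted drug cost x full-adherence
        # equivalents, with any scenario adherence scaling
        drug_cost = costing.weighted_drug_cost(p.formulary)
        med = costing.medication_cost(
            fls.n_attendees,
            p.prescription_rate,
            p.adherence,
            drug_cost,
            adherence_scale=sc.adherence_scale,
        )

        stage_costs: dict[Stage, StageCost] = {}
        for st, s in p.stages.items():
            if st is Stage.CLINIC_EXAM_TREATMENT:
                s = dc_replace(s, medication=med)
            stage_costs[st] = s

        fls_stage_per_1000 = {
            st: costing.per_thousand(s.total, fls.n_patients)
            for st, s in stage_costs.items()
        }

        # uptake scenario: fraction u of the usual-care cohort receives
        # clinic + follow-up care at the FLS per-attendee cost
        usual_stage_per_1000 = {st: 0.0 for st in stage_costs}
        if sc.usual_care_uptake > 0:
            if fls.attendance_rate <= 0:
                raise ValueError("uptake scenario requires a non-zero FLS "
                                 "attendance rate")
            scale = sc.usual_care_uptake / fls.attendance_rate
            for st in ATTENDEE_STAGES:
                if st in usual_stage_per_1000:
                    usual_stage_per_1000[st] = scale * fls_stage_per_1000[st]

        # non-responder leakage: a fraction of FLS non-attendees assumed to
        # access equivalent care elsewhere, charged to the FLS arm
        nonresponder_per_1000 = 0.0
        if sc.nonresponder_treated_fraction > 0:
            cost_pp = (
                sc.nonresponder_cost_per_patient
                if sc.nonresponder_cost_per_patient is not None
                else p.nonresponder_cost_per_patient
            )
            nonresp_per_1000 = (fls.n_patients - fls.n_attendees) / fls.n_patients * 1000.0
            nonresponder_per_1000 = (
                sc.nonresponder_treated_fraction * nonresp_per_1000 * cost_pp
            )

        # refracture treatment costs
        unit_costs = {
            c: refracture.unit_cost(rc) for c, rc in p.refracture_categories.items()
        }
        fls_tally = refracture.tally_from_cohort(fls)
        usual_tally = refracture.tally_from_cohort(usual)
        fls_refrac_per_1000 = costing.per_thousand(
            refracture.cohort_refracture_cost(fls_tally, unit_costs), fls.n_patients
        )
        usual_refrac_per_1000 = costing.per_thousand(
            refracture.cohort_refracture_cost(usual_tally, unit_costs),
            usual.n_patients,
        )

        incidence = compare_incidence(
            fls_tally.total, fls.n_patients, usual_tally.total, usual.n_patients
        )

        return FLSCostResults(
            model=self,
            scenario=sc,
            stage_costs=stage_costs,
            fls_stage_per_1000=fls_stage_per_1000,
            usual_stage_per_1000=usual_stage_per_1000,
            fls_refracture_per_1000=fls_refrac_per_1000,
            usual_refracture_per_1000=usual_refrac_per_1000,
            nonresponder_per_1000=nonresponder_per_1000,
            incidence=incidence,
        )


@dataclass(frozen=True)
class FLSCostResults:
    """Per-1000 cost table, net saving and incidence comparison."""

    model: FLSCostModel
    scenario: ScenarioSpec
    stage_costs: dict[Stage, StageCost]
    fls_stage_per_1000: dict[Stage, float]
    usual_stage_per_1000: dict[Stage, float]
    fls_refracture_per_1000: float
    usual_refracture_per_1000: float
    nonresponder_per_1000: float
    incidence: IncidenceResult

    # ---- aggregates ---------------------------------------------------
    @property
    def fls_pathway_per_1000(self) -> float:
        """Total post-ED FLS pathway cost per 1000 (the four stages)."""
        return sum(self.fls_stage_per_1000.values())

    @property
    def usual_pathway_per_1000(self) -> float:
        return sum(self.usual_stage_per_1000.values())

    @property
    def fls_total(self) -> float:
        """FLS arm total per 1000: stages + refractures (+ leakage)."""
        return (
            self.fls_pathway_per_1000
            + self.fls_refracture_per_1000
            + self.nonresponder_per_1000
        )

    @property
    def usual_total(self) -> float:
        return self.usual_pathway_per_1000 + self.usual_refracture_per_1000

    @property
    def net_saving(self) -> float:
        """Usual-care total minus FLS total, per 1000 (positive = FLS saves)."""
        return self.usual_total - self.fls_total

    @property
    def fls_refractures_per_1000(self) -> float:
        return self.incidence.rate_fls * 1000.0

    @property
    def usual_refractures_per_1000(self) -> float:
        return self.incidence.rate_usual * 1000.0

    @property
    def refracture_difference(self) -> float:
        """Refractures avoided per 1000 (usual - FLS)."""
        return self.incidence.diff_per_1000

    # ---- derived analyses ---------------------------------------------
    def percent_change_on_base(self, base: "FLSCostResults | None" = None) -> float:
        """Fractional change of this scenario's saving on the base case."""
        if base is None:
            base = self.model.fit()
        return percent_change_on_base(self.net_saving, base.net_saving)

    def annualize(self, annual_patients: int | None = None) -> float:
        """Scale the per-1000 saving to the annual patient throughput."""
        n = (
            annual_patients
            if annual_patients is not None
            else self.model.params.annual_patients
        )
        return annualize(self.net_saving, n)

    # ---- presentation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-1000 cost table: rows = pathway rows, columns FLS/Usual/net."""
        rows = []
        for st in Stage:
            if st not in self.fls_stage_per_1000:
                continue
            rows.append(
                (
                    _STAGE_LABELS[st],
                    self.fls_stage_per_1000[st],
                    self.usual_stage_per_1000[st],
                )
            )
        rows.append(
            ("Total post-ED FLS costs", self.fls_pathway_per_1000,
             self.usual_pathway_per_1000)
        )
        if self.nonresponder_per_1000:
            rows.append(("Non-responder care elsewhere",
                         self.nonresponder_per_1000, 0.0))
        rows.append(
            ("Refracture treatments", self.fls_refracture_per_1000,
             self.usual_refracture_per_1000)
        )
        rows.append(("Total per 1000 processed patients", self.fls_total,
                     self.usual_total))
        df = pd.DataFrame(rows, columns=["row", "fls", "usual_care"])
        df["fls_net_cost"] = df["fls"] - df["usual_care"]
        return df.set_index("row")

    def summary(self) -> str:
        """Aligned text summary of the comparison (whole-dollar rendering)."""
        from .report import format_results_summary

        return format_results_summary(self)

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {
            "scenario": {
                "usual_care_uptake": self.scenario.usual_care_uptake,
                "adherence_scale": self.scenario.adherence_scale,
                "nonresponder_treated_fraction":
                    self.scenario.nonresponder_treated_fraction,
            },
            "per_1000_costs": {
                row: {
                    "fls": rec["fls"],
                    "usual_care": rec["usual_care"],
                    "fls_net_cost": rec["fls_net_cost"],
                }
                for row, rec in df.to_dict("index").items()
            },
            "fls_total": self.fls_total,
            "usual_total": self.usual_total,
            "net_saving": self.net_saving,
            "refractures_per_1000": {
                "fls": self.fls_refractures_per_1000,
                "usual_care": self.usual_refractures_per_1000,
                "difference": self.refracture_difference,
            },
            "incidence": self.incidence.to_dict(),
        }


# ---------------------------------------------------------------------------
# functional conveniences
# ---------------------------------------------------------------------------


def base_case(params: Parameters | None = None) -> FLSCostResults:
    """Evaluate the base case (usual care receives no preventative care)."""
    return FLSCostModel(params).fit()


def uptake_scenario(params: Parameters | None, uptake: float) -> FLSCostResults:
    """Scenario: a fraction of usual care receives FLS-grade clinic care."""
    return FLSCostModel(params).fit(ScenarioSpec(usual_care_uptake=uptake))


def adherence_sensitivity(params: Parameters | None, scale: float) -> float:
    """Net saving per 1000 after scaling mean medication adherence."""
    return FLSCostModel(params).fit(ScenarioSpec(adherence_scale=scale)).net_saving


def nonresponder_leakage(
    params: Parameters | None,
    treated_fraction: float,
    cost_per_patient: float | None = None,
) -> float:
    """Net saving per 1000 when some FLS non-attendees are treated elsewhere."""
    return (
        FLSCostModel(params)
        .fit(
            ScenarioSpec(
                nonresponder_treated_fraction=treated_fraction,
                nonresponder_cost_per_patient=cost_per_patient,
            )
        )
        .net_saving
    )


def percent_change_on_base(scenario_saving: float, base_saving: float) -> float:
    """Fractional change of a scenario saving relative to the base case."""
    if base_saving == 0:
        raise ZeroDivisionError("base saving is zero")
    return (scenario_saving - base_saving) / base_saving


def annualize(per_1000_saving: float, annual_patients: int) -> float:
    """Convert a per-1000 saving to an annual saving at a given throughput."""
    if annual_patients < 0:
        raise ValueError("annual_patients must be >= 0")
    return per_1000_saving * annual_patients / 1000.0
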