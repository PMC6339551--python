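"""Refracture unit-cost derivation and cohort cost attribution.

Per-category unit costs are derived from national totals (total direct cost
divided by event count), optionally inflated to the analysis reference year,
and applied to each cohort's tallied refracture events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .params import (
    CATEGORIES,
    CohortSpec,
    Parameters,
    PriceIndexSeries,
    RefractureCategoryCost,
)

__all__ = ["RefractureTally", "unit_cost", "cohort_refracture_cost",
           "tally_from_cohort", "category_table"]


@dataclass(frozen=True)
class RefractureTally:
    """Refracture events of one cohort, by category."""

    cohort: str
    counts: dict[str, int]
    n_patients: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def per_1000(self) -> float:
        return self.total / self.n_patients * 1000.0


def tally_from_cohort(c: CohortSpec) -> RefractureTally:
    return RefractureTally(c.name, dict(c.n_refractures_by_category), c.n_patients)


def unit_cost(
    category_data: RefractureCategoryCost,
    index: PriceIndexSeries | None = None,
    from_year: int | None = None,
    target_year: int | None = None,
) -> float:
    """Average direct cost per refracture event in one category.

    national_total_cost / national_count, inflated from ``from_year`` to
    ``target_year`` when an index and both years are given.
    """
    if category_data.national_count <= 0:
        raise ValueError(f"{category_data.category}: national_count must be > 0")
    uc = category_data.national_total_cost / category_data.national_count
    if index is not None and from_year is not None and target_year is not None:
        from .costing import inflate

        uc = inflate(uc, from_year, target_year, index)
    return uc


def cohort_refracture_cost(
    tally: RefractureTally, unit_costs: Mapping[str, float]
) -> float:
    """Whole-cohort refracture treatment cost: sum of count x unit cost."""
    unknown = set(tally.counts) - set(unit_costs)
    if unknown:
        raise KeyError(
            f"no unit cost for categories: {', '.join(sorted(unknown))}"
        )
    return float(sum(n * unit_costs[c] for c, n in tally.counts.items()))


def category_table(params: Parameters) -> pd.DataFrame:
    """Per-category unit-cost table (for CSV export).

    Columns: category, national_total_cost, national_count, unit_cost_2015_16.
    """
    rows = []
    for cat in CATEGORIES:
        rc = params.refracture_categories.get(cat)
        if rc is None:
            continue
        rows.append(
            {
                "category": cat,
                "national_total_cost": rc.national_total_cost,
                "national_count": rc.national_count,
                "unit_cost_2015_16": rc.unit_cost,
            }
        )
    return pd.DataFrame(rows)
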