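"""Publication-style rendering: whole-dollar money formatting and the
base-case + scenarios comparison table.

All internal arithmetic is unrounded; rounding half-up to whole dollars
happens here and only here.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .model import FLSCostResults, _STAGE_LABELS
from .params import Stage

__all__ = ["round_aud", "fmt_money", "render_table2", "format_results_summary"]


def round_aud(x: float) -> int:
    """Round to whole Australian dollars, half away from zero."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def fmt_money(x: float) -> str:
    """Whole-dollar currency: thousands separators, ASCII leading minus."""
    r = round_aud(x)
    return f"-${abs(r):,}" if r < 0 else f"${r:,}"


_ROW_STAGES = [
    Stage.ED_RECORD_ASSESSMENT,
    Stage.PATIENT_GP_CONTACT,
    Stage.CLINIC_EXAM_TREATMENT,
    Stage.FOLLOWUP_CALLS,
]


def render_table2(
    base: FLSCostResults, scenarios: Sequence[FLSCostResults]
) -> pd.DataFrame:
    """Comparison table: base case plus uptake scenarios, per-1000 costs.

    Rows: the four FLS pathway stages, the pathway total, refracture
    treatments, the grand total, the percent change on the base case, and
    refractures per 1000.  Columns: the FLS arm, then for the base case and
    each scenario a usual-care column and an "FLS net cost" column
    (FLS minus usual care).  Values are unrounded floats; use
    :func:`render_table2_text` or :func:`fmt_money` for whole-dollar output.
    """
    all_results = [base, *scenarios]
    rows: list[dict] = []

    def add_row(label: str, fls_val, usual_vals) -> None:
        rec: dict = {"row": label, "FLS": fls_val}
        for res, uv in zip(all_results, usual_vals):
            tag = _scenario_tag(res, base)
            rec[f"{tag}: Usual Care"] = uv
            rec[f"{tag}: FLS net cost"] = (
                fls_val - uv if fls_val is not None and uv is not None else None
            )
        rows.append(rec)

    for st in _ROW_STAGES:
        if st not in base.fls_stage_per_1000:
            continue
        add_row(
            _STAGE_LABELS[st],
            base.fls_stage_per_1000[st],
            [r.usual_stage_per_1000.get(st, 0.0) for r in all_results],
        )
    add_row(
        "Total post-ED FLS costs",
        base.fls_pathway_per_1000,
        [r.usual_pathway_per_1000 for r in all_results],
    )
    add_row(
        "Refracture treatments",
        base.fls_refracture_per_1000,
        [r.usual_refracture_per_1000 for r in all_results],
    )
    add_row(
        "Total per 1000 processed patients",
        base.fls_total,
        [r.usual_total for r in all_results],
    )
    # change on base: defined for scenarios only, on the net saving
    rec: dict = {"row": "Change on base case", "FLS": None}
    for res in all_results:
        tag = _scenario_tag(res, base)
        rec[f"{tag}: Usual Care"] = None
        rec[f"{tag}: FLS net cost"] = (
            None if res is base else res.percent_change_on_base(base)
        )
    rows.append(rec)
    add_row(
        "Refractures per 1000 processed ED patients",
        base.fls_refractures_per_1000,
        [r.usual_refractures_per_1000 for r in all_results],
    )
    return pd.DataFrame(rows).set_index("row")


def _scenario_tag(res: FLSCostResults, base: FLSCostResults) -> str:
    if res is base:
        return "Base case"
    u = res.scenario.usual_care_uptake
    return f"{u:.0%} uptake"


def render_table2_text(base: FLSCostResults,
                       scenarios: Sequence[FLSCostResults]) -> str:
    """Aligned text rendering of :func:`render_table2` (whole dollars)."""
    df = render_table2(base, scenarios)

    def cell(row: str, v) -> str:
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        if row == "Change on base case":
            return f"{100 * v:.1f}%"
        if row.startswith("Refractures per 1000"):
            return f"{round_aud(v):,}"
        return fmt_money(v)

    out = df.copy().astype(object)
    for row in out.index:
        for col in out.columns:
            out.loc[row, col] = cell(row, df.loc[row, col])
    return _align(out)


def _align(df: pd.DataFrame) -> str:
    """Minimal fixed-width table renderer (right-aligned numeric cells)."""
    headers = ["", *df.columns]
    body = [[str(i), *[("" if v is None else str(v)) for v in rec]]
            for i, rec in zip(df.index, df.itertuples(index=False))]
    widths = [max(len(r[j]) for r in [headers, *body]) for j in range(len(headers))]
    lines = []
    for k, row in enumerate([headers, *body]):
        cells = [row[0].ljust(widths[0])]
        cells += [c.rjust(w) for c, w in zip(row[1:], widths[1:])]
        lines.append("  ".join(cells).rstrip())
        if k == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines)


def format_results_summary(res: FLSCostResults) -> str:
    """Compact text summary of one comparison result."""
    df = res.to_frame()
    lines = ["FLS vs Usual Care - per 1000 processed patients (AUD 2015-16)"]
    sc = res.scenario
    if sc.usual_care_uptake or sc.adherence_scale != 1.0 or \
            sc.nonresponder_treated_fraction:
        lines.append(
            f"scenario: uptake={sc.usual_care_uptake:.0%}, "
            f"adherence x{sc.adherence_scale:g}, "
            f"non-responder fraction={sc.nonresponder_treated_fraction:.0%}"
        )
    lines.append("")
    w = max(len(i) for i in df.index) + 2
    lines.append(f"{'':{w}}{'FLS':>14}{'Usual care':>14}{'FLS net cost':>14}")
    for row, rec in df.iterrows():
        lines.append(
            f"{row:{w}}{fmt_money(rec['fls']):>14}"
            f"{fmt_money(rec['usual_care']):>14}"
            f"{fmt_money(rec['fls_net_cost']):>14}"
        )
    lines.append("")
    lines.append(f"Net saving (usual care - FLS): {fmt_money(res.net_saving)}")
    lines.append(
        "Refractures per 1000: FLS "
        f"{round_aud(res.fls_refractures_per_1000)}, usual care "
        f"{round_aud(res.usual_refractures_per_1000)} "
        f"(difference {round_aud(res.refracture_difference)})"
    )
    inc = res.incidence
    lines.append(
        f"Relative risk {inc.relative_risk:.2f} "
        f"(95% CI {inc.rr_ci[0]:.2f}-{inc.rr_ci[1]:.2f}), "
        f"Poisson rate-ratio p = {inc.rate_ratio_p:.3f}"
    )
    return "\n".join(lines)
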