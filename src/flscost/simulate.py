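"""Synthetic patient-level cohorts with the study's statistical structure.

Each generated cohort emulates the observable structure of the two real
cohorts: patients aged 50+, ~75% female, a 20% FLS clinic attendance rate,
66.66% prescription among attendees, nested year-end persistence
(50/35/25%), and per-patient refracture event counts drawn as Poisson with
mean equal to the target 3-year clinical incidence (so a patient can
refracture more than once, matching the event-count framing of clinical
incidence).  Refracture categories are multinomial, uniform across
hip/vertebral/wrist/other by default, with event days uniform over the
3-year horizon.

A ``fixed_fraction`` mode makes all headcounts exact (round(n * rate))
rather than binomial, so deterministic downstream checks are
seed-independent.

Records are plain :class:`pandas.DataFrame` tables; refracture events are
encoded per patient as a semicolon-joined ``category:day`` string so a
cohort round-trips through a single CSV file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CATEGORIES, CohortSpec
from .refracture import RefractureTally

__all__ = ["CohortGenSpec", "generate_cohort", "tabulate",
           "write_cohort", "read_cohort", "events_frame"]

#: Column order of a patient-records table.
COLUMNS = [
    "id", "cohort", "age", "sex", "ses_decile", "attended_fls", "prescribed",
    "persist_y1", "persist_y2", "persist_y3", "refractures",
]

HORIZON_DAYS = 3 * 365


@dataclass(frozen=True)
class CohortGenSpec:
    """Generation parameters for one synthetic cohort."""

    name: str = "FLS"
    n: int = 515
    incidence: float = 0.150  # mean refracture events per patient over 3 years
    attendance_rate: float = 0.20  # 0 for a usual-care cohort
    prescription_rate: float = 0.6666
    persistence: tuple[float, ...] = (0.50, 0.35, 0.25)
    female_fraction: float = 0.75
    median_age: float = 78.0
    category_mix: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CATEGORIES}
    )
    fixed_fraction: bool = False

    def invariant_errors(self) -> list[str]:
        errs = []
        if self.n <= 0:
            errs.append("n must be > 0")
        if self.incidence < 0:
            errs.append("incidence must be >= 0")
        for nm in ("attendance_rate", "prescription_rate", "female_fraction"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{nm} {v} outside [0, 1]")
        if any(not (0.0 <= f <= 1.0) for f in self.persistence):
            errs.append("persistence fractions outside [0, 1]")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            errs.append("category_mix must sum to 1")
        return errs


def _exact_count(n: int, rate: float) -> int:
    return int(round(n * rate))


def generate_cohort(spec: CohortGenSpec, seed: int = 0) -> pd.DataFrame:
    """Generate one synthetic cohort as a patient-records table.

    Deterministic given ``(spec, seed)``.  In ``fixed_fraction`` mode the
    attendee, prescription and total-refracture counts equal round(n * rate)
    exactly; otherwise they are binomial/Poisson draws.
    """
    errs = spec.invariant_errors()
    if errs:
        raise ValueError("invalid cohort generation spec: " + "; ".join(errs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = spec.n

    age = np.maximum(50.0, rng.normal(spec.median_age, 10.0, size=n)).round(1)
    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    ses = rng.integers(1, 11, size=n)

    if spec.fixed_fraction:
        attended = np.zeros(n, dtype=bool)
        k = _exact_count(n, spec.attendance_rate)
        attended[rng.choice(n, size=k, replace=False)] = True
        prescribed = np.zeros(n, dtype=bool)
        idx = np.flatnonzero(attended)
        kp = _exact_count(len(idx), spec.prescription_rate)
        prescribed[rng.choice(idx, size=kp, replace=False)] = True
    else:
        attended = rng.random(n) < spec.attendance_rate
        prescribed = attended & (rng.random(n) < spec.prescription_rate)

    # nested persistence: one latent uniform per patient; persisting at
    # year-end k iff u < persistence[k] (non-increasing schedule => nested)
    u = rng.random(n)
    persist = {
        f"persist_y{k + 1}": prescribed & (u < frac)
        for k, frac in enumerate(spec.persistence)
    }

    if spec.fixed_fraction:
        total_events = _exact_count(n, spec.incidence)
        owners = rng.integers(0, n, size=total_events)
        counts = np.bincount(owners, minlength=n)
    else:
        counts = rng.poisson(spec.incidence, size=n)
        total_events = int(counts.sum())

    cats = list(spec.category_mix)
    probs = np.array([spec.category_mix[c] for c in cats])
    event_cats = rng.choice(cats, size=total_events, p=probs) if total_events else []
    event_days = rng.integers(1, HORIZON_DAYS + 1, size=total_events)

    refrac_strings = [""] * n
    pos = 0
    for i in range(n):
        c = counts[i]
        if c:
            toks = [f"{event_cats[j]}:{event_days[j]}" for j in range(pos, pos + c)]
            refrac_strings[i] = ";".join(toks)
            pos += c

    df = pd.DataFrame(
        {
            "id": [f"{spec.name}-{i:05d}" for i in range(n)],
            "cohort": spec.name,
            "age": age,
            "sex": sex,
            "ses_decile": ses,
            "attended_fls": attended,
            "prescribed": prescribed,
            **persist,
            "refractures": refrac_strings,
        }
    )
    return df[COLUMNS]


def events_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format refracture events: columns id, category, day."""
    rows = []
    for pid, enc in zip(records["id"], records["refractures"]):
        if not isinstance(enc, str) or not enc:
            continue
        for tok in enc.split(";"):
            cat, day = tok.rsplit(":", 1)
            rows.append({"id": pid, "category": cat, "day": int(day)})
    return pd.DataFrame(rows, columns=["id", "category", "day"])


def tabulate(records: pd.DataFrame) -> tuple[CohortSpec, RefractureTally]:
    """Tally a single-cohort records table into (CohortSpec, RefractureTally).

    Counts patients, attendees and refracture events by category, exactly
    consistent with the records.  Every canonical category appears in the
    tally even at count zero.
    """
    if records.empty:
        raise ValueError("empty records table")
    cohorts = records["cohort"].unique()
    if len(cohorts) != 1:
        raise ValueError(f"mixed cohorts in records: {sorted(cohorts)}")
    name = str(cohorts[0])
    ev = events_frame(records)
    counts = {c: 0 for c in CATEGORIES}
    if not ev.empty:
        for cat, cnt in ev["category"].value_counts().items():
            counts[str(cat)] = counts.get(str(cat), 0) + int(cnt)
    spec = CohortSpec(
        name=name,
        n_patients=len(records),
        n_attendees=int(records["attended_fls"].sum()),
        n_refractures_by_category=counts,
    )
    return spec, RefractureTally(name, dict(counts), len(records))


def write_cohort(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a patient-records table as CSV (documented header)."""
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a patient-records CSV written by :func:`write_cohort`."""
    df = pd.read_csv(
        path,
        dtype={"id": str, "cohort": str, "sex": str, "refractures": str},
        keep_default_na=False,
    )
    for col in ("attended_fls", "prescribed", "persist_y1", "persist_y2",
                "persist_y3"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1"})
    return df[COLUMNS]
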