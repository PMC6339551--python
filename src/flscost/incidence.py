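"""Clinical incidence, relative risk and a two-group Poisson rate-ratio test.

The significance test is the Wald test on the log rate ratio from the
two-group Poisson log-linear model, in closed form: for event counts a, b
with exposures (cohort sizes) E_a, E_b,

    log RR = log((a / E_a) / (b / E_b)),   se = sqrt(1/a + 1/b),

z = log RR / se, with a two-sided normal p-value and
CI95 = exp(log RR +/- 1.96 se).  This is identical to fitting a Poisson
regression with a group indicator and an exposure offset (model-based
standard errors).  When either count is zero the Wald form is undefined and
an exact conditional binomial test is used instead: conditional on a + b
total events, a ~ Binomial(a + b, E_a / (E_a + E_b)) under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "clinical_incidence",
    "relative_risk",
    "poisson_rate_ratio_test",
    "RateRatioTest",
    "IncidenceResult",
    "compare_incidence",
]

_Z95 = stats.norm.ppf(0.975)


def clinical_incidence(n_events: int, n_patients: int) -> float:
    """Events per cohort member over the horizon (full cohort denominator)."""
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return n_events / n_patients


def relative_risk(rate_a: float, rate_b: float) -> float:
    """Ratio of two incidence rates (a relative to b)."""
    if rate_b <= 0:
        raise ValueError("comparator rate must be > 0")
    return rate_a / rate_b


@dataclass(frozen=True)
class RateRatioTest:
    """Result of the two-group Poisson rate-ratio significance test."""

    rate_ratio: float
    log_rr: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    method: str  # "wald" or "exact-binomial"


def poisson_rate_ratio_test(
    events_a: int, exposure_a: float, events_b: int, exposure_b: float
) -> RateRatioTest:
    """Test H0: equal event rates in two groups under a Poisson model.

    Returns the Wald test on the log rate ratio; falls back to the exact
    conditional binomial test when either event count is zero.
    """
    for name, v in (("events_a", events_a), ("events_b", events_b)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    for name, v in (("exposure_a", exposure_a), ("exposure_b", exposure_b)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")

    if events_a == 0 or events_b == 0:
        # Exact conditional test; the rate ratio may be 0 or infinite.
        n = events_a + events_b
        p0 = exposure_a / (exposure_a + exposure_b)
        p = stats.binomtest(events_a, n, p0).pvalue if n > 0 else 1.0
        if events_b == 0 and events_a == 0:
            rr, log_rr = math.nan, math.nan
        elif events_b == 0:
            rr, log_rr = math.inf, math.inf
        else:
            rr, log_rr = 0.0, -math.inf
        return RateRatioTest(
            rate_ratio=rr,
            log_rr=log_rr,
            se=math.nan,
            z=math.nan,
            p=float(p),
            ci95=(math.nan, math.nan),
            method="exact-binomial",
        )

    rr = (events_a / exposure_a) / (events_b / exposure_b)
    log_rr = math.log(rr)
    se = math.sqrt(1.0 / events_a + 1.0 / events_b)
    z = log_rr / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (math.exp(log_rr - _Z95 * se), math.exp(log_rr + _Z95 * se))
    return RateRatioTest(rr, log_rr, se, z, float(p), ci, "wald")


@dataclass(frozen=True)
class IncidenceResult:
    """Incidence comparison of two cohorts over the study horizon."""

    rate_fls: float
    rate_usual: float
    relative_risk: float
    diff_per_1000: float
    rate_ratio_p: float
    rr_ci: tuple[float, float]
    test: RateRatioTest

    def to_dict(self) -> dict:
        return {
            "rate_fls": self.rate_fls,
            "rate_usual": self.rate_usual,
            "relative_risk": self.relative_risk,
            "diff_per_1000": self.diff_per_1000,
            "rate_ratio_p": self.rate_ratio_p,
            "rr_ci": list(self.rr_ci),
            "method": self.test.method,
        }


def compare_incidence(
    events_fls: int, n_fls: int, events_usual: int, n_usual: int
) -> IncidenceResult:
    """Full incidence comparison: rates, RR, per-1000 difference and test."""
    rate_f = clinical_incidence(events_fls, n_fls)
    rate_u = clinical_incidence(events_usual, n_usual)
    test = poisson_rate_ratio_test(events_fls, n_fls, events_usual, n_usual)
    return IncidenceResult(
        rate_fls=rate_f,
        rate_usual=rate_u,
        relative_risk=relative_risk(rate_f, rate_u) if rate_u > 0 else math.nan,
        diff_per_1000=(rate_u - rate_f) * 1000.0,
        rate_ratio_p=test.p,
        rr_ci=test.ci95,
        test=test,
    )
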