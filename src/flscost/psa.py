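"""Monte Carlo probabilistic sensitivity analysis (PSA).

Parameter uncertainty is propagated through the cost model by drawing from
per-parameter distributions and re-evaluating the base-case comparison and
incidence for every draw.  Each draw yields a point (net saving per 1000,
relative refracture risk); the joint cloud is summarised by the fractions
falling in the four quadrants of the cost-effect plane.  The "win-win"
quadrant is a net saving for the FLS (FLS cost - usual-care cost < 0) with
fewer refractures (relative risk FLS/usual < 1).

Default distributions (calibrated to the printed cohort data; the original
study's simulation parameter file is not public):

* cohort refracture event counts resampled as Poisson around the observed
  totals (77 FLS, 88 usual care), scaling each arm's refracture cost
  proportionally and driving the relative risk;
* each pathway stage's cost scaled by a gamma multiplier with mean 1 and a
  20% coefficient of variation.

Reproducibility: one root seed; every distribution draws from its own
sub-stream derived from the target name, so adding or removing one
distribution does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import Parameters, Stage
from .model import FLSCostModel, FLSCostResults

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "default_distributions",
    "sample_draw",
    "run_psa",
]

_FAMILIES = {"fixed", "gamma", "beta", "lognormal", "uniform", "poisson"}

#: Recognised draw targets and how they enter the model re-evaluation.
#: ``stage.<stage>.cost_scale`` - multiplier on that stage's per-1000 cost;
#: ``fls.refracture_events`` / ``usual.refracture_events`` - resampled event
#: totals (refracture cost scales proportionally, incidence recomputed).


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling distribution attached to one model parameter.

    ``family`` is one of fixed, gamma, beta, lognormal, uniform, poisson;
    ``hyper`` holds family-specific hyperparameters:

    * fixed: ``value``
    * gamma: ``mean`` and ``cv`` (or ``variance``)
    * beta: ``mean`` and ``kappa`` (concentration)
    * lognormal: ``mean`` and ``cv``
    * uniform: ``low``, ``high``
    * poisson: ``mean``
    """

    target: str
    family: str
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.target}: unknown family '{self.family}'")
        h = self.hyper
        if self.family == "gamma":
            if h.get("mean", 0) <= 0:
                raise ValueError(f"{self.target}: gamma mean must be > 0")
            if "cv" not in h and "variance" not in h:
                raise ValueError(f"{self.target}: gamma needs cv or variance")
            if h.get("cv", 1) < 0 or h.get("variance", 1) < 0:
                raise ValueError(f"{self.target}: negative dispersion")
        elif self.family == "beta":
            if not (0 < h.get("mean", -1) < 1) or h.get("kappa", 0) <= 0:
                raise ValueError(f"{self.target}: beta needs mean in (0,1), kappa > 0")
        elif self.family == "lognormal":
            if h.get("mean", 0) <= 0 or h.get("cv", -1) < 0:
                raise ValueError(f"{self.target}: lognormal needs mean > 0, cv >= 0")
        elif self.family == "uniform":
            if h.get("low", 0) > h.get("high", 0):
                raise ValueError(f"{self.target}: uniform low > high")
        elif self.family == "poisson":
            if h.get("mean", -1) < 0:
                raise ValueError(f"{self.target}: poisson mean must be >= 0")
        elif self.family == "fixed":
            if "value" not in h:
                raise ValueError(f"{self.target}: fixed needs a value")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        h = self.hyper
        if self.family == "fixed":
            return np.full(n, float(h["value"]))
        if self.family == "gamma":
            mean = float(h["mean"])
            var = float(h["variance"]) if "variance" in h else (mean * h["cv"]) ** 2
            if var == 0:
                return np.full(n, mean)
            shape = mean**2 / var
            return rng.gamma(shape, var / mean, size=n)
        if self.family == "beta":
            a = h["mean"] * h["kappa"]
            b = (1.0 - h["mean"]) * h["kappa"]
            return rng.beta(a, b, size=n)
        if self.family == "lognormal":
            mean, cv = float(h["mean"]), float(h["cv"])
            if cv == 0:
                return np.full(n, mean)
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        if self.family == "uniform":
            return rng.uniform(h["low"], h["high"], size=n)
        # poisson
        return rng.poisson(float(h["mean"]), size=n).astype(float)


def _stream(seed: int, target: str) -> np.random.Generator:
    """Independent, name-keyed RNG sub-stream under a single root seed."""
    key = zlib.crc32(target.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_distributions(params: Parameters | None = None,
                          cost_cv: float = 0.20) -> list[ParameterDistribution]:
    """Calibrated default PSA distributions (see module docstring)."""
    p = params if params is not None else FLSCostModel().params
    dists = [
        ParameterDistribution(
            "fls.refracture_events", "poisson", {"mean": p.fls.n_refractures}
        ),
        ParameterDistribution(
            "usual.refracture_events", "poisson", {"mean": p.usual.n_refractures}
        ),
    ]
    for st in Stage:
        if st in p.stages:
            dists.append(
                ParameterDistribution(
                    f"stage.{st.value}.cost_scale", "gamma",
                    {"mean": 1.0, "cv": cost_cv},
                )
            )
    return dists


def _sample_all(
    dists: Sequence[ParameterDistribution], n: int, seed: int
) -> dict[str, np.ndarray]:
    seen: set[str] = set()
    out: dict[str, np.ndarray] = {}
    for d in dists:
        if d.target in seen:
            raise ValueError(f"duplicate distribution target '{d.target}'")
        seen.add(d.target)
        out[d.target] = d.sample(n, _stream(seed, d.target))
    return out


def sample_draw(
    dists: Sequence[ParameterDistribution],
    seed: int,
    params: Parameters | None = None,
) -> dict[str, float]:
    """Draw one full set of sampled parameter values.

    Returns a mapping of every recognised target to its drawn value;
    targets without a distribution keep their base-case values (refracture
    event totals and unit stage-cost multipliers).
    """
    p = params if params is not None else FLSCostModel().params
    base: dict[str, float] = {
        "fls.refracture_events": float(p.fls.n_refractures),
        "usual.refracture_events": float(p.usual.n_refractures),
    }
    for st in p.stages:
        base[f"stage.{st.value}.cost_scale"] = 1.0
    draws = _sample_all(dists, 1, seed)
    base.update({t: float(v[0]) for t, v in draws.items()})
    return base


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws of (net saving, relative risk) and their summary."""

    draws: pd.DataFrame  # columns: iteration, net_saving, relative_risk
    n_iterations: int
    seed: int
    quadrant_fractions: dict[str, float]
    summary: dict[str, float]

    @property
    def win_win_fraction(self) -> float:
        """Fraction of draws with an FLS saving and fewer refractures."""
        return self.quadrant_fractions["saving_fewer_refractures"]

    @property
    def win_win_se(self) -> float:
        """Binomial standard error of the win-win fraction."""
        f = self.win_win_fraction
        return float(np.sqrt(f * (1.0 - f) / self.n_iterations))

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "quadrant_fractions": dict(self.quadrant_fractions),
            "win_win_fraction": self.win_win_fraction,
            "win_win_se": self.win_win_se,
            "net_saving": dict(self.summary),
        }


def run_psa(
    params: Parameters | None = None,
    dists: Sequence[ParameterDistribution] | None = None,
    n_iterations: int = 2000,
    seed: int = 0,
) -> PSAResult:
    """Run the Monte Carlo PSA and summarise the cost-effect plane.

    For every draw the base-case comparison is rebuilt with the sampled
    stage-cost multipliers and resampled refracture event totals, and the
    (net saving per 1000, relative risk) pair is recorded.  Deterministic
    given (seed, n_iterations, dists).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    model = FLSCostModel(params)
    p = model.params
    base = model.fit()
    if dists is None:
        dists = default_distributions(p)
    draws = _sample_all(dists, n_iterations, seed)
    ones = np.ones(n_iterations)

    def get(target: str, default: np.ndarray) -> np.ndarray:
        return draws.get(target, default)

    # pathway stage costs (FLS arm), scaled per draw
    fls_pathway = np.zeros(n_iterations)
    for st, per1000 in base.fls_stage_per_1000.items():
        fls_pathway += per1000 * get(f"stage.{st.value}.cost_scale", ones)

    # refracture event totals drive both refracture costs and incidence
    base_a = float(p.fls.n_refractures)
    base_b = float(p.usual.n_refractures)
    a = get("fls.refracture_events", np.full(n_iterations, base_a))
    b = get("usual.refracture_events", np.full(n_iterations, base_b))
    fls_refrac = base.fls_refracture_per_1000 * np.divide(a, base_a)
    usual_refrac = base.usual_refracture_per_1000 * np.divide(b, base_b)

    fls_total = fls_pathway + fls_refrac
    usual_total = usual_refrac
    net_saving = usual_total - fls_total
    net_cost = -net_saving

    rate_f = a / p.fls.n_patients
    rate_u = b / p.usual.n_patients
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(rate_u > 0, rate_f / rate_u, np.inf)
        rr = np.where((rate_u == 0) & (rate_f == 0), np.nan, rr)

    fewer = rr < 1.0  # NaN compares False: a degenerate 0/0 draw is not a win
    saving = net_cost < 0.0
    frac = {
        "saving_fewer_refractures": float(np.mean(saving & fewer)),
        "saving_more_refractures": float(np.mean(saving & ~fewer)),
        "cost_fewer_refractures": float(np.mean(~saving & fewer)),
        "cost_more_refractures": float(np.mean(~saving & ~fewer)),
    }

    df = pd.DataFrame(
        {
            "iteration": np.arange(n_iterations),
            "net_saving": net_saving,
            "relative_risk": rr,
        }
    )
    lo, med, hi = np.percentile(net_saving, [2.5, 50.0, 97.5])
    summary = {
        "mean": float(np.mean(net_saving)),
        "median": float(med),
        "p2.5": float(lo),
        "p97.5": float(hi),
    }
    return PSAResult(
        draws=df,
        n_iterations=n_iterations,
        seed=seed,
        quadrant_fractions=frac,
        summary=summary,
    )


def plot_psa(result: PSAResult, path: str, base: FLSCostResults | None = None):
    """Scatter of net FLS cost against relative risk (cost-effect plane).

    Requires matplotlib (optional dependency); writes a PNG/PDF to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        result.draws["relative_risk"],
        -result.draws["net_saving"],
        s=6,
        alpha=0.4,
        edgecolors="none",
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(1.0, color="grey", lw=0.8)
    if base is not None:
        ax.scatter([base.incidence.relative_risk], [-base.net_saving],
                   color="red", marker="x", zorder=3, label="base case")
        ax.legend(frameon=False)
    ax.set_xlabel("Relative refracture risk (FLS / usual care)")
    ax.set_ylabel("Net FLS cost per 1000 patients (AUD)")
    ax.set_title(
        f"PSA ({result.n_iterations} iterations): "
        f"{100 * result.win_win_fraction:.1f}% saving with fewer refractures"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
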