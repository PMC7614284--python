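"""Synthetic datasets with the exact generative structure the model assumes.

True transition-rate curves are built from the same spline family the
model fits (smooth log-linear trends in age with mild curvature), tuned
to magnitudes typical of a common chronic disease: incidence rising from
~1/2500 per year in middle age to ~1/75 at the oldest ages, and case
fatality from ~2% to ~15%.  Observed counts are then exact binomial
draws from the implied outcome probabilities, so fitting the matching
model variant to its own simulated data is a well-posed parameter
recovery problem.

Default denominators mimic aggregate national or city-region data:
tens of thousands at risk per year of age for incidence and mortality,
a couple of thousand sampled for prevalence, all decaying sharply above
age 90 so the "estimates are highly uncertain at the oldest ages"
regime is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CountData, ModelConfig
from .process import RateSchedule, TrendMatrix, cohort_outcome_probabilities, outcome_probabilities
from .splines import SplineBasis, rate_basis, rate_curve

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "default_denominators",
    "make_true_rates",
    "simulate_dataset",
    "simulate_scenario",
]

VARIANTS = ("single-area", "hierarchical", "gendered", "gendered-interaction", "trended")

# true spline coefficients (intercept, slope on age/A, curvature terms):
# case fatality rises ~0.026 -> 0.14 over ages 50..100 and incidence
# ~0.001 -> 0.009 over 30..100 with a plateau at the oldest ages
_CF_BETA = np.array([np.log(0.005), 3.0, 0.08, -0.05, 0.03, 0.0, 0.0, 0.0, 0.0, 0.0])
_INC_BETA = np.array([np.log(4e-4), 3.5, -0.10, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])

A_BASE = {"cf": 50, "inc": 30, "rem": 0}


@dataclass(frozen=True)
class ScenarioConfig:
    """What to generate: model variant, true parameters, sizes, seed."""

    variant: str = "single-area"
    A: int = 100
    K: int = 10
    seed: int = 0
    n_area: int = 4
    lambda1: float = 0.3          # between-area SD of log case-fatality intercepts
    male_intercept: float = 0.5   # additive male offset on log rates
    male_slope: float = 0.3
    #: per-area male intercept offsets for the interaction variant
    interaction_offsets: tuple = (0.7, -0.5, 0.3, -0.3)
    remission_rate: float = 0.0   # constant remission if > 0
    denominators: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant '{self.variant}'; one of {VARIANTS}")
        if self.denominators:
            for m, v in self.denominators.items():
                if np.any(np.asarray(v) < 0):
                    raise ValueError(f"denominators for '{m}' must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """True rates per group plus everything needed to score a fit."""

    scenario: ScenarioConfig
    bases: dict                   # rate name -> SplineBasis on its age range
    rates: dict                   # (area, gender) -> RateSchedule
    beta: dict                    # (area, gender) -> {"cf": ..., "inc": ...}
    trends: tuple | None = None   # (TrendMatrix incidence, TrendMatrix case fatality)

    def outcome_probs(self, group) -> "OutcomeProbabilities":
        sched = self.rates[group]
        if self.trends is not None:
            return cohort_outcome_probabilities(sched, *self.trends)
        return outcome_probabilities(sched)


def default_denominators(A: int = 100, remission: bool = False) -> dict:
    """Population-scale denominators by age, decaying above age 90."""
    ages = np.arange(A + 1)
    taper = np.clip(1.0 - (ages - 90) / 10.0 * 0.9, 0.1, 1.0)
    dens = {
        "inc": np.round(50_000 * taper).astype(int),
        "mort": np.round(50_000 * taper).astype(int),
        "prev": np.round(2_000 * taper).astype(int),
    }
    if remission:
        dens["rem"] = np.round(1_000 * taper).astype(int)
    return dens


def _curves(bases, beta_cf, beta_inc, A, rem_rate):
    f = rate_curve(beta_cf, bases["cf"], a_base=A_BASE["cf"])
    i = rate_curve(beta_inc, bases["inc"], a_base=A_BASE["inc"])
    r = np.full(A + 1, rem_rate)
    return RateSchedule(i=i, f=f, r=r)


def make_true_rates(scenario: ScenarioConfig) -> SyntheticTruth:
    """Smooth positive true rate curves for every group in the scenario.

    Hierarchical scenarios draw area-specific case-fatality intercepts
    from N(b1, lambda1^2); gendered scenarios add male offsets on the log
    scale (a common offset, or area-specific ones in the interaction
    variant).  Deterministic given the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    A, K = scenario.A, scenario.K
    # the same per-rate bases the matching model uses, so the truth lies
    # exactly in the family being fitted
    bases = {r: rate_basis(A, K, A_BASE[r]) for r in ("cf", "inc")}
    cf0, inc0 = _CF_BETA[:K].copy(), _INC_BETA[:K].copy()

    rates, beta = {}, {}
    trends = None

    def add(area, gender, cf, inc):
        rates[(area, gender)] = _curves(bases, cf, inc, A, scenario.remission_rate)
        beta[(area, gender)] = {"cf": cf.copy(), "inc": inc.copy()}

    if scenario.variant == "single-area":
        add("all", "all", cf0, inc0)
    elif scenario.variant == "trended":
        add("all", "all", cf0, inc0)
        years = np.array([0, 50, 100])
        # past incidence and case fatality higher than today, more so at
        # younger ages: a mild, age-dependent declining trend
        ages = np.arange(A + 1)
        shape = 1.0 + 0.5 * (1.0 - ages / A)[:, None]
        ratios_i = np.hstack([shape * 1.6, shape * 1.2, np.ones((A + 1, 1))])[:, [0, 1, 2]]
        ratios_f = np.hstack([shape * 1.4, shape * 1.1, np.ones((A + 1, 1))])[:, [0, 1, 2]]
        trends = (
            TrendMatrix.from_year_ratios(A, years, ratios_i),
            TrendMatrix.from_year_ratios(A, years, ratios_f),
        )
    elif scenario.variant == "hierarchical":
        offsets = rng.normal(0.0, scenario.lambda1, scenario.n_area)
        for a in range(scenario.n_area):
            cf = cf0.copy()
            cf[0] += offsets[a]
            add(f"area{a}", "all", cf, inc0)
    else:  # gendered variants: areas x (female, male)
        offsets = rng.normal(0.0, scenario.lambda1, scenario.n_area)
        for a in range(scenario.n_area):
            cf = cf0.copy()
            cf[0] += offsets[a]
            if scenario.variant == "gendered":
                male_icpt = scenario.male_intercept
            else:
                male_icpt = scenario.interaction_offsets[a % len(scenario.interaction_offsets)]
            cf_m = cf.copy()
            cf_m[0] += male_icpt
            cf_m[1] += scenario.male_slope
            inc_m = inc0.copy()
            inc_m[0] += male_icpt
            add(f"area{a}", "female", cf, inc0)
            add(f"area{a}", "male", cf_m, inc_m)

    return SyntheticTruth(
        scenario=scenario, bases=bases, rates=rates, beta=beta, trends=trends
    )


def simulate_dataset(
    truth: SyntheticTruth,
    denominators: dict | None = None,
    seed: int = 0,
) -> CountData:
    """Binomial count draws from the truth's outcome probabilities."""
    sc = truth.scenario
    if denominators is None:
        denominators = dict(default_denominators(sc.A, remission=sc.remission_rate > 0))
        denominators.update(sc.denominators)
    rng = np.random.default_rng(seed)
    rows = []
    for (area, gender) in sorted(truth.rates):
        out = truth.outcome_probs((area, gender))
        for measure, dens in denominators.items():
            dens = np.broadcast_to(np.asarray(dens, dtype=int), (sc.A + 1,))
            p = out.for_measure(measure)
            y = rng.binomial(dens, p)
            for age in range(sc.A + 1):
                rows.append((area, gender, age, measure, int(y[age]), int(dens[age])))
    return CountData(
        pd.DataFrame(rows, columns=["area", "gender", "age", "measure", "num", "denom"])
    )


def simulate_scenario(scenario: ScenarioConfig, data_seed: int | None = None):
    """Convenience: truth plus one simulated dataset."""
    truth = make_true_rates(scenario)
    data = simulate_dataset(
        truth, seed=scenario.seed if data_seed is None else data_seed
    )
    return truth, data


def matching_config(scenario: ScenarioConfig, **overrides) -> ModelConfig:
    """The ModelConfig whose structure matches a scenario's generative truth."""
    kwargs = dict(
        A=scenario.A,
        K=scenario.K,
        a_base={"cf": A_BASE["cf"], "inc": A_BASE["inc"]},
        remission="constant" if scenario.remission_rate > 0 else "none",
    )
    if scenario.variant == "hierarchical":
        kwargs["hierarchical"] = True
    elif scenario.variant == "gendered":
        kwargs["gender"] = "additive"
        kwargs["hierarchical"] = scenario.n_area >= 2
    elif scenario.variant == "gendered-interaction":
        kwargs["gender"] = "interaction"
        kwargs["hierarchical"] = scenario.n_area >= 2
    kwargs.update(overrides)
    return ModelConfig(**kwargs)
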