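"""Joint Bayesian model: binomial likelihood, priors, and group structure.

The observable data are counts ``y`` out of ``n`` at each age for up to
four outcome measures — incidence, prevalence, mortality and remission —
optionally split by area and gender.  Each measure follows a binomial
distribution whose probability is a deterministic function (through the
illness-death process) of the age-specific transition rates:

* ``y_inc  ~ Binomial(n, 1 - P_{a,1,1})``
* ``y_prev ~ Binomial(n, pi_a)``
* ``y_mort ~ Binomial(n, d_a)``
* ``y_rem  ~ Binomial(n, P_{a,2,1})``

Log rates are spline functions of age (see :mod:`illnessdeath.splines`).
Areas can be pooled through a hierarchical model on the case-fatality
intercepts, gender can enter as an additive offset on the log scale
(common to all areas) or interact with area, and published calendar-time
trends can fix how past rates relate to current ones.

:func:`assemble_model` returns a :class:`ModelSpec` exposing the
unconstrained parameter layout, log prior, the deterministic map from
parameters to rates and outcome probabilities, and the pointwise
log-likelihood — everything an inference engine needs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import optimize, stats

from .process import (
    N_TREND_YEARS,
    OutcomeProbabilities,
    RateSchedule,
    TrendMatrix,
    cohort_outcome_probabilities,
    mortality_prob,
    transition_prob_array,
)
from .splines import SplineBasis, rate_basis, rate_curve, thinplate_basis

logger = logging.getLogger(__name__)

__all__ = [
    "Z975",
    "MEASURES",
    "CountData",
    "PriorSet",
    "GammaPrior",
    "ModelConfig",
    "ModelSpec",
    "ConfigurationError",
    "elicit_area_sd_prior",
    "log_likelihood",
    "assemble_model",
    "load_config",
]

#: 97.5% standard normal quantile used throughout prior elicitation.
Z975 = 1.959964

MEASURES = ("inc", "prev", "mort", "rem")

RATES = ("inc", "cf", "rem")


class ConfigurationError(ValueError):
    """Model configuration inconsistent with the data or itself."""


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class CountData:
    """Validated count records: (area, gender, age, measure, num, denom)."""

    frame: pd.DataFrame

    REQUIRED = ("age", "measure", "num", "denom")

    def __post_init__(self):
        df = self.frame.copy()
        for col, default in (("area", "all"), ("gender", "all")):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"count data missing columns: {missing}")
        df = df[["area", "gender", "age", "measure", "num", "denom"]].copy()
        bad = ~df["measure"].isin(MEASURES)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValueError(
                f"unknown measure labels {sorted(df.loc[bad, 'measure'].unique())} "
                f"at rows {rows}; expected one of {MEASURES}"
            )
        for col in ("age", "num", "denom"):
            vals = df[col].to_numpy()
            if not np.all(np.isfinite(vals.astype(float))):
                raise ValueError(f"column '{col}' contains non-finite values")
            if np.any(np.mod(vals.astype(float), 1) != 0):
                raise ValueError(f"column '{col}' must be integer-valued")
            df[col] = vals.astype(int)
        if (df["num"] < 0).any() or (df["denom"] < 0).any():
            raise ValueError("numerators and denominators must be nonnegative")
        if (df["num"] > df["denom"]).any():
            rows = df.index[(df["num"] > df["denom"])].tolist()[:5]
            raise ValueError(f"numerator exceeds denominator at rows {rows}")
        if (df["age"] < 0).any():
            raise ValueError("ages must be nonnegative")
        keys = ["area", "gender", "age", "measure"]
        if df.duplicated(keys).any():
            dup = df[df.duplicated(keys, keep=False)].head()
            raise ValueError(f"duplicate (area, gender, age, measure) records:\n{dup}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def areas(self) -> list:
        return sorted(self.frame["area"].unique())

    @property
    def genders(self) -> list:
        return sorted(self.frame["gender"].unique())

    @property
    def measures(self) -> list:
        return sorted(self.frame["measure"].unique())

    @property
    def max_age(self) -> int:
        return int(self.frame["age"].max())

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, scale) prior for a positive scale parameter."""

    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def ppf(self, q: float) -> float:
        return float(stats.gamma.ppf(q, self.shape, scale=self.scale))

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        k, s = self.shape, self.scale
        return np.sum(
            (k - 1.0) * np.log(x) - x / s - k * math.log(s) - gammaln(k)
        )


def elicit_area_sd_prior(ratio_guess: float, ratio_upper: float) -> GammaPrior:
    """Translate fold-ratio beliefs into a gamma prior on the between-area SD.

    "High-risk" and "low-risk" areas are the 2.5% and 97.5% quantiles of
    the between-area log-rate distribution, so their rate ratio is
    ``exp(2 z_{0.975} lambda_1)``.  The returned gamma prior has its
    *mean* matching ``ratio_guess`` and its 97.5% quantile matching
    ``ratio_upper`` on that fold-ratio scale, found by a numerical search
    over the gamma shape.
    """
    if not (1.0 < ratio_guess < ratio_upper):
        raise ValueError(
            f"need 1 < ratio_guess < ratio_upper, got ({ratio_guess}, {ratio_upper})"
        )
    mean_sd = math.log(ratio_guess) / (2.0 * Z975)
    target_q = math.log(ratio_upper) / (2.0 * Z975)

    def q975(log_shape: float) -> float:
        k = math.exp(log_shape)
        return float(stats.gamma.ppf(0.975, k, scale=mean_sd / k))

    # At fixed mean the 97.5% quantile is not monotone in the shape: it
    # tends to 0 as shape -> 0 (mass piles up at zero), rises to a peak,
    # and decreases to the mean as shape -> infinity.  Solve on the
    # decreasing branch, which gives the least extreme prior.
    grid = np.linspace(-12.0, 12.0, 241)
    qs = np.array([q975(g) for g in grid])
    i_peak = int(np.argmax(qs))
    if qs[i_peak] < target_q:
        raise RuntimeError(
            "gamma elicitation infeasible: requested upper fold-ratio "
            f"{ratio_upper} implies a 97.5% quantile {target_q:.4g} above the "
            f"maximum attainable {qs[i_peak]:.4g} at this mean"
        )
    gap = lambda g: q975(g) - target_q
    log_shape = optimize.brentq(gap, grid[i_peak], grid[-1], xtol=1e-13, rtol=1e-15)
    shape = math.exp(log_shape)
    prior = GammaPrior(shape=shape, scale=mean_sd / shape)

    implied_guess = math.exp(2.0 * Z975 * prior.mean)
    implied_upper = math.exp(2.0 * Z975 * prior.ppf(0.975))
    for implied, target, what in (
        (implied_guess, ratio_guess, "guess"),
        (implied_upper, ratio_upper, "upper limit"),
    ):
        if abs(implied - target) / target > 1e-6:
            raise RuntimeError(
                f"gamma elicitation did not converge: implied {what} ratio "
                f"{implied:.8g} vs requested {target:.8g}"
            )
    return prior


@dataclass(frozen=True)
class PriorSet:
    """Prior settings for every parameter block.

    Scales are standard deviations.  ``gender_scale = 0.82`` on the
    additive male intercept and slope offsets puts 95% prior probability
    on a male/female rate ratio (and ratio of age trends) between about
    0.2 and 5.
    """

    intercept_sd: float = 100.0
    slope_sd: float = 100.0
    smooth_shape: float = 2.0      # Gamma(2, 1) prior on lambda_0
    smooth_scale: float = 1.0
    hier_intercept_mean_sd: float = 10.0   # b_1 ~ N(0, 10^2)
    hier_slope_mean: float = 5.0           # b_2 ~ N(5, 5^2)
    hier_slope_sd: float = 5.0
    gender_scale: float = 0.82
    lambda0_male: float = 1.0              # fixed scale of nonlinear gender offsets
    area_sd_prior: GammaPrior | None = None  # on lambda_1; default elicit(5, 50)

    def resolved_area_sd_prior(self) -> GammaPrior:
        if self.area_sd_prior is not None:
            return self.area_sd_prior
        return elicit_area_sd_prior(5.0, 50.0)


# ---------------------------------------------------------------------------
# configuration


def _rate_dict(value, default):
    if value is None:
        return {r: default for r in RATES}
    if isinstance(value, dict):
        out = {r: default for r in RATES}
        for k, v in value.items():
            if k not in RATES:
                raise ConfigurationError(f"unknown rate '{k}' (expected one of {RATES})")
            out[k] = v
        return out
    return {r: value for r in RATES}


@dataclass(frozen=True)
class ModelConfig:
    """Variant flags and structural settings for one model fit."""

    A: int = 100
    K: int = 10
    hierarchical: bool = False
    gender: str = "none"            # none | additive | interaction
    remission: str = "none"         # none | constant | spline
    a_base: dict = field(default_factory=dict)
    increasing: dict = field(default_factory=dict)
    fixed_smooth: dict = field(default_factory=dict)   # rate -> fixed lambda_0
    male_label: str = "male"
    priors: PriorSet = field(default_factory=PriorSet)
    seed: int = 1

    def __post_init__(self):
        if self.gender not in ("none", "additive", "interaction"):
            raise ConfigurationError(f"unknown gender mode '{self.gender}'")
        if self.remission not in ("none", "constant", "spline"):
            raise ConfigurationError(f"unknown remission mode '{self.remission}'")
        object.__setattr__(self, "a_base", _rate_dict(self.a_base or None, 0))
        object.__setattr__(self, "increasing", _rate_dict(self.increasing or None, False))
        fs = {r: None for r in RATES}
        fs.update(self.fixed_smooth or {})
        object.__setattr__(self, "fixed_smooth", fs)
        if self.A < 1 or self.K < 3:
            raise ConfigurationError("need A >= 1 and K >= 3")
        for r in RATES:
            if not (0 <= self.a_base[r] <= self.A):
                raise ConfigurationError(f"a_base[{r}] outside 0..{self.A}")


def load_config(path) -> ModelConfig:
    """Read a ModelConfig from a YAML or JSON file."""
    text = open(path).read()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    raw = dict(raw or {})
    prior_kwargs = raw.pop("priors", {}) or {}
    area_ratio = prior_kwargs.pop("area_ratio_guess", None)
    area_upper = prior_kwargs.pop("area_ratio_upper", None)
    priors = PriorSet(**prior_kwargs)
    if area_ratio is not None:
        priors = replace(priors, area_sd_prior=elicit_area_sd_prior(area_ratio, area_upper))
    return ModelConfig(priors=priors, **raw)


# ---------------------------------------------------------------------------
# binomial likelihood


def _binom_pointwise(y, n, logC, p):
    """Binomial log pmf with the conventions: n = 0 contributes exactly 0;
    impossible data (p = 0 with y > 0, or p = 1 with y < n) yield -inf."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(p), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
    ll = logC + t1 + t2
    return np.where(n == 0, 0.0, ll)


def log_likelihood(data: CountData, probs_by_group) -> tuple[float, np.ndarray]:
    """Total and pointwise binomial log-likelihood.

    ``probs_by_group`` maps each (area, gender) pair appearing in the
    data to an :class:`OutcomeProbabilities` covering all its ages.
    Returns ``(total, pointwise)`` with pointwise values aligned to the
    rows of ``data.frame``.
    """
    df = data.frame
    y = df["num"].to_numpy(float)
    n = df["denom"].to_numpy(float)
    logC = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    p = np.empty(len(df))
    for (area, gender), sub in df.groupby(["area", "gender"], sort=False):
        try:
            out = probs_by_group[(area, gender)]
        except KeyError:
            raise KeyError(f"no outcome probabilities supplied for group {(area, gender)}")
        for measure, rows in sub.groupby("measure", sort=False):
            p[rows.index] = out.for_measure(measure)[rows["age"].to_numpy()]
    pointwise = _binom_pointwise(y, n, logC, p)
    n_imposs = int(np.sum(np.isneginf(pointwise)))
    if n_imposs:
        logger.warning(
            "%d records have probability 0/1 incompatible with their counts "
            "(log-likelihood -inf)", n_imposs,
        )
    return float(np.sum(pointwise)), pointwise


# ---------------------------------------------------------------------------
# parameter layout


@dataclass(frozen=True)
class _Block:
    name: str
    size: int
    offset: int


class ParamLayout:
    """Maps named parameter blocks to slices of the unconstrained vector."""

    def __init__(self):
        self.blocks: dict[str, _Block] = {}
        self.n_params = 0

    def add(self, name: str, size: int) -> None:
        self.blocks[name] = _Block(name, size, self.n_params)
        self.n_params += size

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        b = self.blocks[name]
        return theta[b.offset : b.offset + b.size]

    def set(self, theta: np.ndarray, name: str, value) -> None:
        b = self.blocks[name]
        theta[b.offset : b.offset + b.size] = value

    @property
    def param_names(self) -> list[str]:
        names = []
        for b in self.blocks.values():
            if b.size == 1:
                names.append(b.name)
            else:
                names.extend(f"{b.name}[{j}]" for j in range(b.size))
        return names


# ---------------------------------------------------------------------------
# the assembled model


_NORM_CONST = -0.5 * math.log(2.0 * math.pi)


def _normal_logpdf_sum(x, mean, sd) -> float:
    x = np.asarray(x, dtype=float)
    z = (x - mean) / sd
    return float(np.sum(_NORM_CONST - np.log(sd) - 0.5 * z * z))


class ModelSpec:
    """Assembled joint model over an unconstrained parameter space.

    Scale parameters (lambda_0, lambda_1, constant remission rate) are
    sampled on the log scale with the Jacobian included in the log prior,
    so every element of the parameter vector is unconstrained.
    """

    def __init__(
        self,
        config: ModelConfig,
        data: CountData,
        basis: SplineBasis | None = None,
        trends: tuple[TrendMatrix, TrendMatrix] | None = None,
    ):
        self.config = config
        self.data = data
        # each rate gets a basis on its own informative age range
        # (a_base..A); a caller-supplied basis overrides all of them
        self.bases = {
            rate: basis
            if basis is not None
            else rate_basis(config.A, config.K, config.a_base[rate])
            for rate in RATES
        }
        self.basis = basis
        self.trends = trends
        self.priors = config.priors

        self.areas = data.areas
        self.n_area = len(self.areas)
        self.genders = data.genders

        if config.hierarchical and self.n_area < 2:
            raise ConfigurationError("hierarchical model requires at least 2 areas")
        if "rem" in data.measures and config.remission == "none":
            raise ConfigurationError(
                "remission records present but the model excludes remission; "
                "set remission to 'constant' or 'spline'"
            )
        if config.gender == "none" and len(self.genders) > 1:
            raise ConfigurationError(
                f"data contain genders {self.genders} but gender mode is 'none'; "
                "use 'additive' or 'interaction'"
            )
        if config.gender != "none":
            if len(self.genders) != 2 or config.male_label not in self.genders:
                raise ConfigurationError(
                    f"gender mode '{config.gender}' needs two genders including "
                    f"'{config.male_label}', got {self.genders}"
                )
        if data.max_age > config.A:
            raise ConfigurationError(
                f"data contain age {data.max_age} > A = {config.A}"
            )

        # groups: cartesian (area, gender) over what the data contain
        self.groups = [(a, g) for a in self.areas for g in self.genders]
        self.group_index = {grp: k for k, grp in enumerate(self.groups)}
        self.n_group = len(self.groups)

        self.modelled_rates = ["cf", "inc"]
        if config.remission == "spline":
            self.modelled_rates.append("rem")

        if self.trends is not None:
            ti, tf = self.trends
            for tm in (ti, tf):
                if tm.rho.shape[0] < config.A + 1:
                    raise ConfigurationError("trend matrices do not cover ages 0..A")
        self._area_sd_prior = (
            self.priors.resolved_area_sd_prior() if config.hierarchical else None
        )

        self._build_layout()
        self._index_data()

    # -- layout -------------------------------------------------------------

    def _build_layout(self):
        # Non-centered parameterisation throughout: nonlinear spline
        # coefficients are lambda_0 * z with z ~ N(0, 1), and hierarchical
        # intercepts are b_1 + lambda_1 * u with u ~ N(0, 1).  This removes
        # the funnel between coefficients and their scale, so the joint
        # posterior mode is well defined and both engines behave.
        c, lay = self.config, ParamLayout()
        K = c.K
        for rate in self.modelled_rates:
            if rate == "cf" and c.hierarchical:
                lay.add("cf_b1", 1)
                lay.add("cf_b2", 1)
                lay.add("cf_log_lambda1", 1)
                lay.add("cf_u", self.n_area)
                lay.add("cf_z", self.n_area * (K - 2))
            else:
                lay.add(f"{rate}_lin", self.n_area * 2)
                lay.add(f"{rate}_z", self.n_area * (K - 2))
            if c.gender != "none" and rate in ("cf", "inc"):
                size = K if c.gender == "additive" else self.n_area * K
                lay.add(f"{rate}_male", size)
            if c.fixed_smooth[rate] is None:
                lay.add(f"{rate}_log_lambda0", 1)
        if c.remission == "constant":
            lay.add("rem_log_rate", 1)
        self.layout = lay

    @property
    def n_params(self) -> int:
        return self.layout.n_params

    @property
    def param_names(self) -> list[str]:
        return self.layout.param_names

    # -- data indexing for the fast likelihood path --------------------------

    def _index_data(self):
        df = self.data.frame
        self._y = df["num"].to_numpy(float)
        self._n = df["denom"].to_numpy(float)
        self._logC = gammaln(self._n + 1) - gammaln(self._y + 1) - gammaln(self._n - self._y + 1)
        self._row_group = np.array(
            [self.group_index[(a, g)] for a, g in zip(df["area"], df["gender"])]
        )
        self._row_age = df["age"].to_numpy(int)
        self._measure_rows = {
            m: np.nonzero((df["measure"] == m).to_numpy())[0] for m in MEASURES
        }

    # -- parameters -> rates --------------------------------------------------

    def _smoothness(self, theta, rate) -> float:
        fixed = self.config.fixed_smooth[rate]
        if fixed is not None:
            return float(fixed)
        return float(np.exp(self.layout.get(theta, f"{rate}_log_lambda0")[0]))

    def _coefficients(self, theta, rate) -> np.ndarray:
        """Coefficient matrix of shape (n_group, K) for one rate."""
        c, K = self.config, self.config.K
        lam0 = self._smoothness(theta, rate)
        if rate == "cf" and c.hierarchical:
            b1 = self.layout.get(theta, "cf_b1")[0]
            b2 = self.layout.get(theta, "cf_b2")[0]
            lam1 = math.exp(self.layout.get(theta, "cf_log_lambda1")[0])
            icpt = b1 + lam1 * self.layout.get(theta, "cf_u")
            nonlin = lam0 * self.layout.get(theta, "cf_z").reshape(self.n_area, K - 2)
            beta_area = np.column_stack([icpt, np.full(self.n_area, b2), nonlin])
        else:
            lin = self.layout.get(theta, f"{rate}_lin").reshape(self.n_area, 2)
            nonlin = lam0 * self.layout.get(theta, f"{rate}_z").reshape(self.n_area, K - 2)
            beta_area = np.column_stack([lin, nonlin])
        if rate == "rem" or c.gender == "none":
            rows = [beta_area[self.areas.index(a)] for a, g in self.groups]
            return np.array(rows)
        if c.gender == "additive":
            male = self.layout.get(theta, f"{rate}_male")
            male_by_area = np.tile(male, (self.n_area, 1))
        else:
            male_by_area = self.layout.get(theta, f"{rate}_male").reshape(self.n_area, K)
        out = np.empty((self.n_group, K))
        for k, (a, g) in enumerate(self.groups):
            ia = self.areas.index(a)
            out[k] = beta_area[ia]
            if g == self.config.male_label:
                out[k] += male_by_area[ia]
        return out

    def rates(self, theta) -> dict:
        """Map an unconstrained parameter vector to per-group rate arrays.

        Returns ``{"i": (G, A+1), "f": (G, A+1), "r": (G, A+1)}``.
        """
        c = self.config
        G, A = self.n_group, c.A
        out = {}
        for rate, key in (("inc", "i"), ("cf", "f")):
            coefs = self._coefficients(theta, rate)
            curves = np.empty((G, A + 1))
            for k in range(G):
                curves[k] = rate_curve(
                    coefs[k], self.bases[rate], a_base=c.a_base[rate],
                    increasing=c.increasing[rate],
                )
            out[key] = curves
        if c.remission == "none":
            out["r"] = np.zeros((G, A + 1))
        elif c.remission == "constant":
            r = np.exp(np.clip(self.layout.get(theta, "rem_log_rate")[0], -300, 30))
            out["r"] = np.full((G, A + 1), r)
        else:
            coefs = self._coefficients(theta, "rem")
            curves = np.empty((G, A + 1))
            for k in range(G):
                curves[k] = rate_curve(
                    coefs[k], self.bases["rem"], a_base=c.a_base["rem"],
                    increasing=c.increasing["rem"],
                )
            out["r"] = curves
        return out

    def group_rate_schedules(self, theta) -> dict:
        rt = self.rates(theta)
        return {
            grp: RateSchedule(i=rt["i"][k], f=rt["f"][k], r=rt["r"][k])
            for grp, k in self.group_index.items()
        }

    # -- rates -> outcome probabilities ---------------------------------------

    def outcome_probs(self, theta) -> dict:
        """Outcome probability arrays per measure, each of shape (G, A+1)."""
        rt = self.rates(theta)
        if self.trends is not None:
            ti, tf = self.trends
            res = {m: np.empty_like(rt["i"]) for m in MEASURES}
            for k in range(self.n_group):
                sched = RateSchedule(i=rt["i"][k], f=rt["f"][k], r=rt["r"][k])
                out = cohort_outcome_probabilities(sched, ti, tf)
                for m in MEASURES:
                    res[m][k] = out.for_measure(m)
            return res
        return _outcomes_batch(rt["i"], rt["f"], rt["r"])

    # -- densities ------------------------------------------------------------

    def log_prior(self, theta) -> float:
        c, pr, K = self.config, self.priors, self.config.K
        lp = 0.0
        for rate in self.modelled_rates:
            lam0 = self._smoothness(theta, rate)
            if c.fixed_smooth[rate] is None:
                loglam = self.layout.get(theta, f"{rate}_log_lambda0")[0]
                lp += GammaPrior(pr.smooth_shape, pr.smooth_scale).logpdf(lam0) + loglam
            if rate == "cf" and c.hierarchical:
                b1 = self.layout.get(theta, "cf_b1")[0]
                b2 = self.layout.get(theta, "cf_b2")[0]
                loglam1 = self.layout.get(theta, "cf_log_lambda1")[0]
                lam1 = math.exp(loglam1)
                lp += _normal_logpdf_sum(b1, 0.0, pr.hier_intercept_mean_sd)
                lp += _normal_logpdf_sum(b2, pr.hier_slope_mean, pr.hier_slope_sd)
                lp += self._area_sd_prior.logpdf(lam1) + loglam1
                lp += _normal_logpdf_sum(self.layout.get(theta, "cf_u"), 0.0, 1.0)
                lp += _normal_logpdf_sum(self.layout.get(theta, "cf_z"), 0.0, 1.0)
            else:
                lin = self.layout.get(theta, f"{rate}_lin").reshape(self.n_area, 2)
                lp += _normal_logpdf_sum(lin[:, 0], 0.0, pr.intercept_sd)
                lp += _normal_logpdf_sum(lin[:, 1], 0.0, pr.slope_sd)
                lp += _normal_logpdf_sum(self.layout.get(theta, f"{rate}_z"), 0.0, 1.0)
            if c.gender != "none" and rate in ("cf", "inc"):
                male = self.layout.get(theta, f"{rate}_male").reshape(-1, K)
                lp += _normal_logpdf_sum(male[:, :2], 0.0, pr.gender_scale)
                lp += _normal_logpdf_sum(male[:, 2:], 0.0, pr.lambda0_male)
        if c.remission == "constant":
            lp += _normal_logpdf_sum(
                self.layout.get(theta, "rem_log_rate"), 0.0, pr.intercept_sd
            )
        return lp

    def prob_rows(self, theta) -> np.ndarray:
        """Modelled outcome probability for every data record."""
        probs = self.outcome_probs(theta)
        p = np.empty(len(self._y))
        for m, rows in self._measure_rows.items():
            if len(rows):
                p[rows] = probs[m][self._row_group[rows], self._row_age[rows]]
        return p

    def loglik_pointwise(self, theta) -> np.ndarray:
        return _binom_pointwise(self._y, self._n, self._logC, self.prob_rows(theta))

    def fisher_weights(self, theta) -> np.ndarray:
        """Expected binomial information n / (p (1 - p)) per record."""
        p = np.clip(self.prob_rows(theta), 1e-12, 1.0 - 1e-12)
        return self._n / (p * (1.0 - p))

    def prior_hessian_diag(self, theta) -> np.ndarray:
        """Diagonal of the negative prior Hessian on the unconstrained space.

        Exact because the non-centered parameterisation makes every prior
        a fixed-scale normal on its own coordinate, except the gamma
        priors on log scale parameters, whose curvature is lambda/scale.
        """
        c, pr = self.config, self.priors
        h = np.empty(self.n_params)
        lay = self.layout
        for rate in self.modelled_rates:
            if rate == "cf" and c.hierarchical:
                lay.set(h, "cf_b1", pr.hier_intercept_mean_sd ** -2)
                lay.set(h, "cf_b2", pr.hier_slope_sd ** -2)
                lam1 = math.exp(lay.get(theta, "cf_log_lambda1")[0])
                lay.set(h, "cf_log_lambda1", lam1 / self._area_sd_prior.scale)
                lay.set(h, "cf_u", 1.0)
                lay.set(h, "cf_z", 1.0)
            else:
                lin = np.empty((self.n_area, 2))
                lin[:, 0] = pr.intercept_sd ** -2
                lin[:, 1] = pr.slope_sd ** -2
                lay.set(h, f"{rate}_lin", lin.ravel())
                lay.set(h, f"{rate}_z", 1.0)
            if c.gender != "none" and rate in ("cf", "inc"):
                male = np.empty((-(-lay.blocks[f"{rate}_male"].size // c.K), c.K))
                male[:, :2] = pr.gender_scale ** -2
                male[:, 2:] = pr.lambda0_male ** -2
                lay.set(h, f"{rate}_male", male.ravel())
            if c.fixed_smooth[rate] is None:
                lam0 = math.exp(lay.get(theta, f"{rate}_log_lambda0")[0])
                lay.set(h, f"{rate}_log_lambda0", lam0 / pr.smooth_scale)
        if c.remission == "constant":
            lay.set(h, "rem_log_rate", pr.intercept_sd ** -2)
        return h

    def prior_grad(self, theta) -> np.ndarray:
        """Gradient of the log prior on the unconstrained space (exact)."""
        c, pr = self.config, self.priors
        g = np.empty(self.n_params)
        lay = self.layout
        for rate in self.modelled_rates:
            if rate == "cf" and c.hierarchical:
                lay.set(g, "cf_b1", -lay.get(theta, "cf_b1") / pr.hier_intercept_mean_sd ** 2)
                lay.set(
                    g, "cf_b2",
                    -(lay.get(theta, "cf_b2") - pr.hier_slope_mean) / pr.hier_slope_sd ** 2,
                )
                lam1 = math.exp(lay.get(theta, "cf_log_lambda1")[0])
                ap = self._area_sd_prior
                lay.set(g, "cf_log_lambda1", ap.shape - lam1 / ap.scale)
                lay.set(g, "cf_u", -lay.get(theta, "cf_u"))
                lay.set(g, "cf_z", -lay.get(theta, "cf_z"))
            else:
                lin = lay.get(theta, f"{rate}_lin").reshape(self.n_area, 2)
                glin = np.column_stack(
                    [-lin[:, 0] / pr.intercept_sd ** 2, -lin[:, 1] / pr.slope_sd ** 2]
                )
                lay.set(g, f"{rate}_lin", glin.ravel())
                lay.set(g, f"{rate}_z", -lay.get(theta, f"{rate}_z"))
            if c.gender != "none" and rate in ("cf", "inc"):
                male = lay.get(theta, f"{rate}_male").reshape(-1, c.K)
                gm = np.empty_like(male)
                gm[:, :2] = -male[:, :2] / pr.gender_scale ** 2
                gm[:, 2:] = -male[:, 2:] / pr.lambda0_male ** 2
                lay.set(g, f"{rate}_male", gm.ravel())
            if c.fixed_smooth[rate] is None:
                lam0 = math.exp(lay.get(theta, f"{rate}_log_lambda0")[0])
                lay.set(
                    g, f"{rate}_log_lambda0", pr.smooth_shape - lam0 / pr.smooth_scale
                )
        if c.remission == "constant":
            lay.set(
                g, "rem_log_rate",
                -lay.get(theta, "rem_log_rate") / pr.intercept_sd ** 2,
            )
        return g

    def loglik_grad_p(self, theta) -> np.ndarray:
        """d log-likelihood / d p per record, at clipped probabilities."""
        p = np.clip(self.prob_rows(theta), 1e-12, 1.0 - 1e-12)
        g = self._y / p - (self._n - self._y) / (1.0 - p)
        return np.where(self._n == 0, 0.0, g)

    def log_posterior(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            return -np.inf
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = float(np.sum(self.loglik_pointwise(theta)))
        if np.isnan(ll):
            return -np.inf
        return lp + ll

    # -- initial values --------------------------------------------------------

    def _crude(self, measure: str, fallback: float) -> float:
        df = self.data.frame
        sub = df[df["measure"] == measure]
        if len(sub) == 0 or sub["denom"].sum() == 0:
            return fallback
        p = sub["num"].sum() / sub["denom"].sum()
        return float(max(p, 1e-8))

    def initial_point(self) -> np.ndarray:
        """Spline coefficients at 0 except intercepts at crude log estimates;
        scale hyperparameters at their prior means."""
        c, pr = self.config, self.priors
        theta = np.zeros(self.n_params)
        p_inc = self._crude("inc", 1e-4)
        p_prev = self._crude("prev", 0.01)
        p_mort = self._crude("mort", 1e-4)
        p_rem = self._crude("rem", 0.05)
        crude = {
            "inc": max(-math.log1p(-min(p_inc, 0.99)), 1e-8),
            "cf": min(max(p_mort / max(p_prev, 1e-4), 1e-6), 10.0),
            "rem": max(-math.log1p(-min(p_rem, 0.99)), 1e-8),
        }
        for rate in self.modelled_rates:
            icpt = math.log(crude[rate])
            if c.increasing[rate]:
                icpt -= math.log(max(c.A - c.a_base[rate], 1))
            if rate == "cf" and c.hierarchical:
                self.layout.set(theta, "cf_b1", icpt)
                lam1 = self._area_sd_prior.mean
                self.layout.set(theta, "cf_log_lambda1", math.log(lam1))
            else:
                lin = np.zeros((self.n_area, 2))
                lin[:, 0] = icpt
                self.layout.set(theta, f"{rate}_lin", lin.ravel())
            if c.fixed_smooth[rate] is None:
                self.layout.set(
                    theta, f"{rate}_log_lambda0",
                    math.log(pr.smooth_shape * pr.smooth_scale),
                )
        if c.remission == "constant":
            self.layout.set(theta, "rem_log_rate", math.log(crude["rem"]))
        return theta


def _outcomes_batch(i_mat, f_mat, r_mat) -> dict:
    """Outcome probabilities for G groups at once; arrays (G, A+1).

    Only the two live states need tracking through the occupancy
    recursion, so it is carried as explicit (G,) vector arithmetic —
    the hot path of every likelihood evaluation.
    """
    G, n_age = i_mat.shape
    P = transition_prob_array(i_mat.ravel(), f_mat.ravel(), r_mat.ravel())
    P = P.reshape(G, n_age, 3, 3)
    p11, p12 = P[:, :, 0, 0], P[:, :, 0, 1]
    p21, p22 = P[:, :, 1, 0], P[:, :, 1, 1]
    S1 = np.empty((G, n_age))
    S2 = np.empty((G, n_age))
    S1[:, 0], S2[:, 0] = 1.0, 0.0
    for a in range(n_age - 1):
        s1, s2 = S1[:, a], S2[:, a]
        S1[:, a + 1] = s1 * p11[:, a] + s2 * p21[:, a]
        S2[:, a + 1] = s1 * p12[:, a] + s2 * p22[:, a]
    alive = S1 + S2
    ok = alive > 1e-12
    pi = np.where(ok, S2 / np.where(ok, alive, 1.0), np.nan)
    if not ok.all():
        # carry the last well-defined prevalence forward within each group
        idx = np.where(ok, np.arange(n_age)[None, :], 0)
        idx = np.maximum.accumulate(idx, axis=1)
        pi = pi[np.arange(G)[:, None], idx]
        logger.debug("cohort numerically extinct in %d cells", int((~ok).sum()))
    return {
        "inc": 1.0 - p11,
        "prev": pi,
        "mort": P[:, :, 1, 2] * pi + P[:, :, 0, 2] * (1.0 - pi),
        "rem": p21,
    }


def assemble_model(
    config: ModelConfig,
    data: CountData,
    basis: SplineBasis | None = None,
    trends: tuple[TrendMatrix, TrendMatrix] | None = None,
) -> ModelSpec:
    """Assemble the joint Bayesian model for the given configuration and data.

    By default each spline-modelled rate gets a basis built on its own
    informative age range (``a_base..A``); pass ``basis`` to override.
    """
    return ModelSpec(config, data, basis, trends)
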