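"""Model checking: conflict p-values, LOO cross-validation, fit tables.

Conflict p-values compare a single observed count against the model's
synthesis of all the evidence: the count alone yields a conjugate
Beta(y + 0.5, n - y + 0.5) posterior for its underlying probability p,
and the tail probability q = Pr(p < p_full) is computed against the
posterior draws of the corresponding modelled probability p_full.  The
two-sided conflict p-value is 2 min(q, 1 - q); small values flag records
whose direct evidence disagrees with the rest of the synthesis.

Predictive comparison of whole models uses the expected log predictive
density (ELPD) estimated by leave-one-out cross-validation with
Pareto-smoothed importance sampling over the pointwise log-likelihood
matrix; higher total ELPD means better predictive fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = ["ConflictResult", "LooResult", "conflict_pvalue", "loo_elpd", "fitted_vs_observed"]


@dataclass(frozen=True)
class ConflictResult:
    """Tail probability and two-sided conflict p-value for one record."""

    q: float
    pvalue: float


def conflict_pvalue(y: int, n: int, p_full_draws) -> ConflictResult:
    """Conflict between one observed count and the modelled probability.

    q is Rao-Blackwellised: the Beta(y + 0.5, n - y + 0.5) posterior CDF
    is averaged over the draws of p_full rather than comparing draw
    against draw, which removes one layer of Monte Carlo noise.  With
    n = 0 the Beta(0.5, 0.5) prior alone is used.
    """
    draws = np.asarray(p_full_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("p_full_draws is empty")
    if np.any((draws < 0) | (draws > 1)):
        raise ValueError("p_full draws must lie in [0, 1]")
    if not (0 <= y <= n):
        raise ValueError(f"need 0 <= y <= n, got y={y}, n={n}")
    q = float(np.mean(stats.beta.cdf(draws, y + 0.5, n - y + 0.5)))
    pvalue = 2.0 * min(q, 1.0 - q)
    return ConflictResult(q=q, pvalue=float(np.clip(pvalue, np.finfo(float).tiny, 1.0)))


@dataclass(frozen=True)
class LooResult:
    """Pointwise and total leave-one-out expected log predictive density."""

    pointwise: np.ndarray
    pareto_k: np.ndarray | None
    method: str

    @property
    def total(self) -> float:
        return float(np.sum(self.pointwise))


def loo_elpd(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws x observations) log-likelihood matrix.

    Importance weights 1 / p(y_i | theta_d) are stabilised by Pareto
    smoothing.  With a single draw, or if the weights degenerate, the
    plain log pointwise predictive density is returned and flagged.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood matrix must be (draws, observations)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite values")
    D, N = ll.shape
    if D == 1:
        return LooResult(pointwise=ll[0].copy(), pareto_k=None, method="single_draw")
    spread = ll.max(axis=0) - ll.min(axis=0)
    if np.all(spread < 1e-12):
        logger.warning("identical log-likelihood across draws; returning plain lpd")
        lpd = logsumexp(ll, axis=0) - np.log(D)
        return LooResult(pointwise=lpd, pareto_k=None, method="degenerate_lpd")

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from arviz.stats import psislw

        # input (obs, draws): last axis is the sample dimension
        lw, k = psislw(-ll.T)
        lw = np.asarray(lw)
        k = np.asarray(k)
    # psislw returns normalised smoothed log weights; elpd_i = lse(lw_i + ll_i)
    pointwise = logsumexp(lw + ll.T, axis=1)
    n_bad = int(np.sum(k > 0.7))
    if n_bad:
        logger.warning("PSIS pareto-k > 0.7 for %d observations; LOO may be unstable", n_bad)
    return LooResult(pointwise=pointwise, pareto_k=k, method="psis")


def fitted_vs_observed(fit, data=None, point: str = "median") -> pd.DataFrame:
    """Per-record comparison of observed proportions with fitted probabilities.

    One row per (area, gender, age, measure): observed y, n and
    proportion, fitted probability (posterior median by default, or the
    value at the mode), 95% interval, and the conflict p-value.  Records
    with n = 0 are excluded (logged).
    """
    from .engines import probability_draws

    model = fit.model
    if data is None:
        data = model.data
    p_draws = probability_draws(fit, data)
    df = data.frame.copy()

    n0 = df["denom"] == 0
    if n0.any():
        logger.info("excluding %d records with denominator 0 from the fit table", int(n0.sum()))

    lo, mid, hi = np.quantile(p_draws, [0.025, 0.5, 0.975], axis=0)
    if point == "mode" and hasattr(fit, "mode"):
        mid = probability_draws_at_mode(fit)
    df["observed"] = df["num"] / df["denom"].replace(0, np.nan)
    df["fitted"] = mid
    df["fitted_lower"] = lo
    df["fitted_upper"] = hi
    df["conflict_p"] = [
        conflict_pvalue(y, n, p_draws[:, j]).pvalue if n > 0 else np.nan
        for j, (y, n) in enumerate(zip(df["num"], df["denom"]))
    ]
    return df[~n0.to_numpy()].reset_index(drop=True)


def probability_draws_at_mode(fit) -> np.ndarray:
    """Modelled probability per record evaluated exactly at the posterior mode."""
    model = fit.model
    out = model.outcome_probs(fit.mode)
    p = np.empty(len(model.data))
    for m, rows in model._measure_rows.items():
        if len(rows):
            p[rows] = out[m][model._row_group[rows], model._row_age[rows]]
    return p
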