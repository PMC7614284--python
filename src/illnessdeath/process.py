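"""Deterministic mathematics of the three-state illness-death process.

States are 1 = disease-free, 2 = disease, 3 = dead from the disease.
Transition rates between states are piecewise-constant within integer
years of age: incidence ``i_a`` (1 -> 2), remission ``r_a`` (2 -> 1) and
case fatality ``f_a`` (2 -> 3).  Death from other causes is excluded by
construction, so state 3 counts only disease-specific deaths.

This module maps rate schedules to annual transition probability
matrices, state occupancy of a hypothetical birth cohort, and the
outcome probabilities (incidence probability, prevalence, mortality,
remission probability) that generate observable count data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RateSchedule",
    "TrendMatrix",
    "OutcomeProbabilities",
    "intensity_matrix",
    "annual_transition_probs",
    "transition_prob_array",
    "state_occupancy",
    "prevalence",
    "mortality_prob",
    "outcome_probabilities",
    "cohort_outcome_probabilities",
]

#: Number of calendar-year columns in a trend matrix: years 0..100,
#: where year 100 is the year of the data.
N_TREND_YEARS = 101

_DEAD_ROW = np.array([0.0, 0.0, 1.0])


def _check_rate(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"rate '{name}' must be finite, got {value!r}")
    if np.any(arr < 0):
        raise ValueError(f"rate '{name}' must be >= 0, got {value!r}")


@dataclass(frozen=True)
class RateSchedule:
    """Age-specific transition rates, the estimand of the whole model.

    Rates are per person-year and constant on each age interval
    ``[a, a+1)`` for integer ages ``a = 0..A``.
    """

    i: np.ndarray
    f: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        i = np.asarray(self.i, dtype=float)
        f = np.asarray(self.f, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if not (i.shape == f.shape == r.shape) or i.ndim != 1:
            raise ValueError("rate arrays must be 1-d and share a length")
        for arr, name in ((i, "i"), (f, "f"), (r, "r")):
            _check_rate(arr, name)
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "r", r)

    @property
    def max_age(self) -> int:
        return len(self.i) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.i))


@dataclass(frozen=True)
class OutcomeProbabilities:
    """Per-age probabilities generating the four observable outcomes."""

    inc: np.ndarray   # 1 - P_{a,1,1}: probability of onset within the year
    prev: np.ndarray  # pi_a: prevalence among the living
    mort: np.ndarray  # d_a: disease-specific death probability among the living
    rem: np.ndarray   # P_{a,2,1}: annual probability of moving disease -> health

    def for_measure(self, measure: str) -> np.ndarray:
        return getattr(self, measure)


def intensity_matrix(i: float, f: float, r: float) -> np.ndarray:
    """Instantaneous transition intensity matrix Q for one year of age.

    Rows: (-i, i, 0), (r, -(r+f), f), (0, 0, 0).  Death is absorbing and
    unreachable directly from the disease-free state.
    """
    for val, name in ((i, "i"), (f, "f"), (r, "r")):
        _check_rate(val, name)
    return np.array(
        [
            [-i, i, 0.0],
            [r, -(r + f), f],
            [0.0, 0.0, 0.0],
        ]
    )


def transition_prob_array(i, f, r) -> np.ndarray:
    """Annual transition probability matrices for vectors of rates.

    The matrix exponential ``expm(Q)`` of the intensity matrix has a
    closed form here: the live-state (2x2) block ``M`` of Q satisfies
    ``expm(M) = exp(tau) [cosh(d) I + sinh(d)/d (M - tau I)]`` with
    ``tau = trace(M)/2`` and ``d = sqrt(tau^2 - det(M))``; the
    discriminant ``tau^2 - det M = ((i + r - f)^2 + 4 r f)/4`` is always
    nonnegative so ``d`` is real.  The dead column follows from row sums.

    Returns an array of shape ``(n, 3, 3)``.
    """
    i = np.atleast_1d(np.asarray(i, dtype=float))
    f = np.atleast_1d(np.asarray(f, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    for arr, name in ((i, "i"), (f, "f"), (r, "r")):
        _check_rate(arr, name)

    tau = -(i + r + f) / 2.0
    disc = tau * tau - i * f
    d = np.sqrt(np.maximum(disc, 0.0))

    # exp(tau) cosh(d) and exp(tau) sinh(d)/d written via exp(tau +/- d),
    # both of which lie in [0, 1] (tau <= 0 and d <= |tau|): overflow-safe
    # for arbitrarily large rates.
    E1 = np.exp(tau + d)
    E2 = np.exp(tau - d)
    ecosh = 0.5 * (E1 + E2)
    small = d < 1e-6
    d_safe = np.where(small, 1.0, d)
    esinhc = np.where(
        small,
        np.exp(tau) * (1.0 + d * d / 6.0),
        0.5 * (E1 - E2) / d_safe,
    )

    # expm of the 2x2 live block
    p11 = ecosh + esinhc * (-i - tau)
    p12 = esinhc * i
    p21 = esinhc * r
    p22 = ecosh + esinhc * (-(r + f) - tau)

    n = len(i)
    P = np.zeros((n, 3, 3))
    P[:, 0, 0] = p11
    P[:, 0, 1] = p12
    P[:, 1, 0] = p21
    P[:, 1, 1] = p22
    # absorb rounding: clip live entries then give the remainder to death
    np.clip(P[:, :2, :2], 0.0, 1.0, out=P[:, :2, :2])
    P[:, 0, 2] = np.clip(1.0 - p11 - p12, 0.0, 1.0)
    P[:, 1, 2] = np.clip(1.0 - p21 - p22, 0.0, 1.0)
    P[:, 2, 2] = 1.0
    return P


def annual_transition_probs(i: float, f: float, r: float) -> np.ndarray:
    """Annual 3x3 transition probability matrix for scalar rates."""
    return transition_prob_array(i, f, r)[0]


DEFAULT_S0 = np.array([1.0, 0.0, 0.0])


def _check_s0(S0) -> np.ndarray:
    S0 = np.asarray(S0, dtype=float)
    if S0.shape != (3,) or np.any(S0 < 0) or abs(S0.sum() - 1.0) > 1e-10:
        raise ValueError(f"S0 must be a length-3 probability vector, got {S0!r}")
    return S0


def state_occupancy(rates: RateSchedule, S0=DEFAULT_S0) -> np.ndarray:
    """State occupancy S_a for a birth cohort, a = 0..A, via S_{a+1} = S_a P_a."""
    S0 = _check_s0(S0)
    P = transition_prob_array(rates.i, rates.f, rates.r)
    A = rates.max_age
    S = np.empty((A + 1, 3))
    S[0] = S0
    for a in range(A):
        S[a + 1] = S[a] @ P[a]
    return S


def prevalence(S_a) -> float | np.ndarray:
    """Prevalence pi_a = S_{a,2} / (S_{a,1} + S_{a,2}) among the living."""
    S_a = np.asarray(S_a, dtype=float)
    alive = S_a[..., 0] + S_a[..., 1]
    if np.any(alive <= 0):
        raise ValueError("prevalence undefined: no probability mass alive")
    return S_a[..., 1] / alive


def mortality_prob(P_a: np.ndarray, pi_a) -> float | np.ndarray:
    """Population mortality probability d_a = P_{a,2,3} pi_a + P_{a,1,3} (1 - pi_a)."""
    pi_a = np.asarray(pi_a, dtype=float)
    if np.any(pi_a < 0) or np.any(pi_a > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    return P_a[..., 1, 2] * pi_a + P_a[..., 0, 2] * (1.0 - pi_a)


_ALIVE_FLOOR = 1e-12


def _prevalence_path(S: np.ndarray) -> np.ndarray:
    """Per-age prevalence, carrying the last defined value forward once the
    hypothetical cohort has (numerically) died out."""
    alive = S[:, 0] + S[:, 1]
    ok = alive > _ALIVE_FLOOR
    pi = np.zeros(len(S))
    pi[ok] = S[ok, 1] / alive[ok]
    if not ok.all():
        bad = np.nonzero(~ok)[0]
        last = None
        for a in range(len(S)):
            if ok[a]:
                last = pi[a]
            elif last is not None:
                pi[a] = last
        logger.warning(
            "cohort numerically extinct at ages %s; carrying last prevalence forward",
            bad.tolist(),
        )
    return pi


def outcome_probabilities(rates: RateSchedule, S0=DEFAULT_S0) -> OutcomeProbabilities:
    """All four observable outcome probabilities by age, no time trends."""
    S0 = _check_s0(S0)
    P = transition_prob_array(rates.i, rates.f, rates.r)
    A = rates.max_age
    S = np.empty((A + 1, 3))
    S[0] = S0
    for a in range(A):
        S[a + 1] = S[a] @ P[a]
    pi = _prevalence_path(S)
    return OutcomeProbabilities(
        inc=1.0 - P[:, 0, 0],
        prev=pi,
        mort=mortality_prob(P, pi),
        rem=P[:, 1, 0],
    )


@dataclass(frozen=True)
class TrendMatrix:
    """Published ratios of a rate in calendar year y to its current-year value.

    ``rho[a, y]`` for ages 0..A (rows) and years 0..100 (columns); year
    100 is the year of the data, so ``rho[:, 100] == 1``.
    """

    rho: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 2 or rho.shape[1] != N_TREND_YEARS:
            raise ValueError(
                f"trend matrix must have {N_TREND_YEARS} year columns, got shape {rho.shape}"
            )
        if not np.all(np.isfinite(rho)) or np.any(rho <= 0):
            raise ValueError("trend ratios must be positive and finite")
        if not np.allclose(rho[:, -1], 1.0, atol=1e-12):
            raise ValueError("current-year (y=100) trend ratios must all equal 1")
        object.__setattr__(self, "rho", rho)

    @classmethod
    def ones(cls, A: int) -> "TrendMatrix":
        return cls(np.ones((A + 1, N_TREND_YEARS)))

    @classmethod
    def from_year_ratios(cls, A: int, years, ratios_by_age) -> "TrendMatrix":
        """Build a full age x year grid from ratios known at a subset of years.

        ``years`` are year offsets in 0..100; ``ratios_by_age`` has shape
        (A+1, len(years)).  Years before the earliest supplied column are
        carried backward; gaps are interpolated linearly on the log-ratio
        scale (constant geometric change between known years).
        """
        years = np.asarray(years, dtype=int)
        vals = np.asarray(ratios_by_age, dtype=float)
        if vals.shape != (A + 1, len(years)):
            raise ValueError("ratios_by_age must have shape (A+1, len(years))")
        if np.any(vals <= 0):
            raise ValueError("trend ratios must be positive")
        order = np.argsort(years)
        years = years[order]
        vals = vals[:, order]
        if years[-1] != N_TREND_YEARS - 1:
            years = np.append(years, N_TREND_YEARS - 1)
            vals = np.hstack([vals, np.ones((A + 1, 1))])
        grid = np.empty((A + 1, N_TREND_YEARS))
        allyears = np.arange(N_TREND_YEARS)
        for a in range(A + 1):
            grid[a] = np.exp(np.interp(allyears, years, np.log(vals[a])))
        # np.interp already carries endpoints flat outside the supplied range
        return cls(grid)

    @classmethod
    def from_csv(cls, path) -> "TrendMatrix":
        """Read a trend matrix from CSV: rows = ages, columns = years 0..100."""
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        import pandas as pd

        A = self.rho.shape[0] - 1
        pd.DataFrame(
            self.rho,
            index=np.arange(A + 1),
            columns=np.arange(N_TREND_YEARS),
        ).to_csv(path)


def cohort_outcome_probabilities(
    current: RateSchedule,
    trend_i: TrendMatrix,
    trend_f: TrendMatrix,
    S0=DEFAULT_S0,
) -> OutcomeProbabilities:
    """Outcome probabilities for the data year when past rates differed.

    Incidence and case fatality in calendar year y are
    ``i_{a,y} = rho^(i)_{a,y} i_a`` and ``f_{a,y} = rho^(f)_{a,y} f_a``.
    Each birth cohort is run forward through its own calendar-specific
    transition matrices via ``S_{a,y} = S_{a-1,y-1} P_{a-1,y-1}``, and all
    outputs refer to the data year y = 100.  Remission is not trended.
    With both trend matrices identically 1 this reduces exactly to
    :func:`outcome_probabilities`.
    """
    S0 = _check_s0(S0)
    A = current.max_age
    for tm, name in ((trend_i, "incidence"), (trend_f, "case fatality")):
        if tm.rho.shape[0] < A + 1:
            raise ValueError(
                f"{name} trend matrix covers ages 0..{tm.rho.shape[0] - 1}, "
                f"but ages 0..{A} are required"
            )

    ny = N_TREND_YEARS
    i_grid = trend_i.rho[: A + 1] * current.i[:, None]   # (A+1, ny)
    f_grid = trend_f.rho[: A + 1] * current.f[:, None]
    r_grid = np.broadcast_to(current.r[:, None], (A + 1, ny))

    P = transition_prob_array(i_grid.ravel(), f_grid.ravel(), r_grid.ravel())
    P = P.reshape(A + 1, ny, 3, 3)

    # Cohort aged c at year 100 was born in year 100 - c; it sees
    # P[b, 100 - c + b] between ages b and b+1.  Advance all cohorts at once.
    S_final = np.tile(S0, (A + 1, 1))  # row c: occupancy of cohort aged c at y=100
    cohorts = np.arange(A + 1)
    for b in range(A):
        active = cohorts[cohorts > b]
        yrs = (ny - 1) - active + b
        Pb = P[b, yrs]  # (n_active, 3, 3)
        S_final[active] = np.einsum("cs,csj->cj", S_final[active], Pb)

    pi = _prevalence_path(S_final)
    P_now = P[:, ny - 1]  # current-year matrices; rho[:,100] = 1
    return OutcomeProbabilities(
        inc=1.0 - P_now[:, 0, 0],
        prev=pi,
        mort=mortality_prob(P_now, pi),
        rem=P_now[:, 1, 0],
    )
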