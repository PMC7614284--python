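"""Spline bases and constrained age curves for log transition rates.

Log rates are modelled as ``log(f_a) = sum_k beta_k g_k(a)`` where the
``g_k`` form a thin-plate-style regression spline basis: an intercept, a
linear term in (scaled) age, and K-2 smooth terms orthogonal to the
linear part whose coefficients are treated as exchangeable N(0, lambda0^2)
draws.  lambda0 controls smoothness: as lambda0 -> 0 the curve collapses
to a straight line on the log scale.

Age is scaled to [0, 1] before basis construction so the slope is the
total log-rate change over the whole age range, which keeps the
documented slope priors (e.g. N(5, 5^2)) on a plausible scale.

Two structural constraints used for sparse data are supported: an age
``a_base`` below which rates are held constant, and an option to force
rates to be nondecreasing above ``a_base`` by building the spline on log
*increments* of the rate rather than log rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasis", "thinplate_basis", "rate_basis", "rate_curve"]


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated spline basis: one row per age, K columns.

    Column 1 is constant, column 2 is scaled age; the remaining columns
    are an orthonormalised cubic radial basis residualised against the
    linear part (so a curve with zero nonlinear coefficients is exactly
    affine in age on the log scale).
    """

    matrix: np.ndarray
    ages: np.ndarray
    K: int
    age_scale: float

    def row_for_age(self, age: int) -> np.ndarray:
        idx = int(age) - int(self.ages[0])
        return self.matrix[idx]


def thinplate_basis(ages, K: int = 10, age_scale: float | None = None) -> SplineBasis:
    """Construct the K-term spline basis on integer ages.

    Knots are evenly spaced over the age range.  The K-2 radial columns
    |x - knot|^3 are residualised against [1, x], orthonormalised, and
    rescaled to O(1) entries, so their coefficients are comparable and
    exchangeable under a common N(0, lambda0^2) prior.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1:
        raise ValueError("ages must be a 1-d array")
    distinct = np.unique(ages)
    if K < 3:
        raise ValueError(f"K must be >= 3, got {K}")
    if len(distinct) < K:
        raise ValueError(
            f"need at least K={K} distinct ages to build a rank-K basis, "
            f"got {len(distinct)}"
        )
    if age_scale is None:
        age_scale = float(ages.max()) if ages.max() > 0 else 1.0
    x = ages / age_scale

    n = len(ages)
    T = np.column_stack([np.ones(n), x])

    knots = np.linspace(x.min(), x.max(), K - 2 + 2)[1:-1]
    E = np.abs(x[:, None] - knots[None, :]) ** 3

    # remove the span of [1, x] so the smooth columns carry only curvature
    coef, *_ = np.linalg.lstsq(T, E, rcond=None)
    E_res = E - T @ coef

    # orthonormalise and rescale; fix signs for determinism
    U, s, _ = np.linalg.svd(E_res, full_matrices=False)
    Z = U[:, : K - 2] * np.sqrt(n)
    for j in range(Z.shape[1]):
        k = np.argmax(np.abs(Z[:, j]))
        if Z[k, j] < 0:
            Z[:, j] = -Z[:, j]

    G = np.column_stack([T, Z])
    return SplineBasis(matrix=G, ages=ages.astype(int), K=K, age_scale=age_scale)


def rate_basis(A: int, K: int = 10, a_base: int = 0) -> SplineBasis:
    """Spline basis for one rate, built on its informative age range.

    The curve is constant below ``a_base``, so the basis spans only ages
    ``a_base..A`` (still scaled by the full range A).  Restricting the
    rows to ages the likelihood can see keeps every basis direction
    identified by the data; a basis spanning the constrained ages as well
    would contain combinations that act only where the curve is never
    evaluated, leaving near-flat directions that are pathological for
    both optimisation and normal approximation.
    """
    return thinplate_basis(np.arange(a_base, A + 1), K=K, age_scale=float(A))


def rate_curve(
    beta,
    basis: SplineBasis,
    a_base: int = 0,
    increasing: bool = False,
) -> np.ndarray:
    """Evaluate a positive per-age rate curve on ages 0..A from coefficients.

    The curve covers all ages from 0 to the last age of the basis.  Below
    ``a_base`` the rate is constant at its value at ``a_base`` (the basis
    is evaluated at ``max(a, a_base)``); the basis itself may span only
    ages ``a_base..A``.  With ``increasing=True`` the spline models log
    increments: ``rate_a = sum_{b = a_base}^{a} exp(s(b))``, anchored so
    that ``rate_{a_base} = exp(s(a_base))``, which is nondecreasing for
    every coefficient vector.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (basis.K,):
        raise ValueError(
            f"coefficient vector has length {len(beta)}, basis has K={basis.K}"
        )
    ages = basis.ages
    if not (0 <= a_base <= ages[-1]):
        raise ValueError(f"a_base={a_base} outside the age range 0..{ages[-1]}")

    out_ages = np.arange(0, ages[-1] + 1)
    base = max(a_base, int(ages[0]))
    eff = np.maximum(out_ages, base)
    # cap log values so extreme coefficient proposals during inference
    # yield huge-but-finite rates rather than overflowing to inf
    if increasing:
        # cumulative exponentiated increments from the base age upward
        upper_idx = np.arange(base - ages[0], len(ages))
        s_upper = np.clip(basis.matrix[upper_idx] @ beta, -300.0, 30.0)
        cums = np.cumsum(np.exp(s_upper))
        return cums[eff - base]
    s = np.clip(basis.matrix[eff - ages[0]] @ beta, -300.0, 30.0)
    return np.exp(s)
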