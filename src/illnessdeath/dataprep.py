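"""Converting published estimate formats into binomial count data.

Published disease burden figures usually arrive as point estimates with
95% uncertainty intervals for 5-year (or wider) age groups.  The
likelihood, however, consumes integer numerators and denominators for
single years of age.  This module provides the bridge:

* :func:`counts_from_estimate` — invert an (estimate, interval) triple to
  the (y, n) pair whose Beta(y + 0.5, n - y + 0.5) posterior interval
  best matches the published interval;
* :func:`disaggregate_age_groups` — split age-group counts into smooth
  one-year counts with a penalised composite-link (Poisson) model,
  rescaled so each group total is conserved exactly;
* :func:`remission_from_survival` — annual remission probability from a
  10-year survival probability;
* :func:`aggregate_areas` — sum counts from districts into regions;
* CSV readers and writers for the documented schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MEASURES, CountData

logger = logging.getLogger(__name__)

__all__ = [
    "EstimateRecord",
    "counts_from_estimate",
    "disaggregate_age_groups",
    "remission_from_survival",
    "aggregate_areas",
    "read_disease_data",
    "read_estimate_data",
    "write_results",
    "prepare_counts",
]


@dataclass(frozen=True)
class EstimateRecord:
    """A published probability estimate with its 95% interval for an age group
    spanning the half-open interval [age_start, age_end)."""

    age_start: int
    age_end: int
    estimate: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValueError(
                f"need 0 <= lower <= estimate <= upper <= 1, got "
                f"({self.lower}, {self.estimate}, {self.upper})"
            )
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")


def _beta_interval(y, n):
    """Jeffreys-style 95% interval of Beta(y + 0.5, n - y + 0.5)."""
    return (
        stats.beta.ppf(0.025, y + 0.5, n - y + 0.5),
        stats.beta.ppf(0.975, y + 0.5, n - y + 0.5),
    )


def counts_from_estimate(record: EstimateRecord) -> tuple[int, int]:
    """Counts (y, n) approximately equivalent to an estimate with 95% interval.

    Searches over the denominator n (with y = round(estimate * n)) for the
    pair whose Beta posterior 95% interval matches the published (lower,
    upper) bounds in squared error.  Wider intervals map to smaller n.
    """
    if record.upper <= record.lower:
        raise ValueError(
            "zero-width interval: cannot infer a sample size; supply a "
            "denominator directly"
        )

    def loss_for(ns: np.ndarray) -> np.ndarray:
        ys = np.round(record.estimate * ns)
        lo, hi = _beta_interval(ys, ns)
        return (lo - record.lower) ** 2 + (hi - record.upper) ** 2

    ns = np.unique(np.geomspace(1, 1e7, 160).astype(np.int64))
    best = ns[int(np.argmin(loss_for(ns)))]
    for span in (1.6, 1.15):
        lo_n, hi_n = max(1, int(best / span)), int(best * span) + 1
        if hi_n - lo_n <= 400:
            ns = np.arange(lo_n, hi_n + 1, dtype=np.int64)
        else:
            ns = np.unique(np.geomspace(lo_n, hi_n, 400).astype(np.int64))
        best = ns[int(np.argmin(loss_for(ns)))]
    n = int(best)
    y = int(np.clip(round(record.estimate * n), 0, n))
    return y, n


# ---------------------------------------------------------------------------
# age-group disaggregation (penalised composite link model)


def _pclm(totals: np.ndarray, C: np.ndarray, lam_grid=None) -> np.ndarray:
    """Smooth yearly Poisson means gamma with C @ gamma fitting group totals.

    Penalised composite-link fit: log gamma carries a second-order
    difference penalty; the penalty weight is chosen by AIC over a grid.
    """
    G, Y = C.shape
    if lam_grid is None:
        lam_grid = 10.0 ** np.arange(0, 7)
    D = np.diff(np.eye(Y), n=2, axis=0)
    DtD = D.T @ D
    mean0 = max(totals.sum(), 1.0) / Y
    best_aic, best_gamma = np.inf, np.full(Y, mean0)
    for lam in lam_grid:
        eta = np.full(Y, np.log(mean0))
        P = lam * DtD
        ok = True
        for _ in range(100):
            gamma = np.exp(np.clip(eta, -30, 30))
            mu = C @ gamma
            mu = np.maximum(mu, 1e-10)
            Q = C * gamma[None, :]
            W = 1.0 / mu
            QtWQ = Q.T @ (Q * W[:, None])
            rhs = Q.T @ (W * (totals - mu)) + QtWQ @ eta - P @ eta
            try:
                eta_new = np.linalg.solve(QtWQ + P + 1e-10 * np.eye(Y), rhs)
            except np.linalg.LinAlgError:
                ok = False
                break
            if np.max(np.abs(eta_new - eta)) < 1e-8:
                eta = eta_new
                break
            eta = eta_new
        if not ok:
            continue
        gamma = np.exp(np.clip(eta, -30, 30))
        mu = np.maximum(C @ gamma, 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(totals > 0, totals * np.log(totals / mu), 0.0)
        dev = 2.0 * np.sum(dev_terms - (totals - mu))
        Q = C * gamma[None, :]
        W = 1.0 / mu
        QtWQ = Q.T @ (Q * W[:, None])
        try:
            ed = np.trace(np.linalg.solve(QtWQ + P + 1e-10 * np.eye(Y), QtWQ))
        except np.linalg.LinAlgError:
            continue
        aic = dev + 2.0 * ed
        if aic < best_aic:
            best_aic, best_gamma = aic, gamma
    return best_gamma


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative values to integers summing exactly to `total`."""
    if total == 0 or values.sum() <= 0:
        return np.zeros(len(values), dtype=int)
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(scaled - floors))
    floors[order[:short]] += 1
    return floors


def _check_groups(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values("age_start").reset_index(drop=True)
    starts = df["age_start"].to_numpy()
    ends = df["age_end"].to_numpy()
    if np.any(ends <= starts):
        raise ValueError("each age group must satisfy age_end > age_start")
    if np.any(starts[1:] != ends[:-1]):
        raise ValueError(
            "age groups must be contiguous and non-overlapping; got "
            f"boundaries {list(zip(starts, ends))}"
        )
    return df


def disaggregate_age_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Split contiguous age-group counts into smooth one-year counts.

    ``groups`` needs columns age_start, age_end (half-open), num, denom.
    Numerators and denominators are each disaggregated with the
    composite-link smoother, rescaled so every group total is conserved
    exactly, and rounded by largest-remainder apportionment.  Returns a
    frame with one row per year of age.
    """
    df = _check_groups(groups[["age_start", "age_end", "num", "denom"]].copy())
    if (df["num"] > df["denom"]).any():
        raise ValueError("numerator exceeds denominator in an age group")
    lo, hi = int(df["age_start"].iloc[0]), int(df["age_end"].iloc[-1])
    years = np.arange(lo, hi)
    Y = len(years)
    C = np.zeros((len(df), Y))
    for g, (s, e) in enumerate(zip(df["age_start"], df["age_end"])):
        C[g, s - lo : e - lo] = 1.0

    out = {}
    for col in ("denom", "num"):
        totals = df[col].to_numpy(float)
        gamma = _pclm(totals, C)
        yearly = np.zeros(Y, dtype=int)
        for g in range(len(df)):
            sel = C[g] > 0
            yearly[sel] = _largest_remainder(gamma[sel], int(totals[g]))
        out[col] = yearly

    # repair any year where rounding pushed num above denom, conserving totals
    num, den = out["num"], out["denom"]
    for g in range(len(df)):
        sel = np.nonzero(C[g] > 0)[0]
        while True:
            over = sel[num[sel] > den[sel]]
            if len(over) == 0:
                break
            j = over[0]
            excess = num[j] - den[j]
            slack = sel[num[sel] < den[sel]]
            if len(slack) == 0:
                raise ValueError("cannot reconcile numerators with denominators")
            k = slack[np.argmax(den[slack] - num[slack])]
            move = min(excess, den[k] - num[k])
            num[j] -= move
            num[k] += move

    return pd.DataFrame({"age": years, "num": num, "denom": den})


def remission_from_survival(s10: float) -> float:
    """Annual remission probability from a 10-year survival probability.

    Survival here means surviving disease for 10 years because remission
    occurred within them: s10 = 1 - (1 - r)^10, so r = 1 - (1 - s10)^(1/10).
    """
    if not 0.0 <= s10 <= 1.0:
        raise ValueError(f"10-year survival probability must be in [0, 1], got {s10}")
    return 1.0 - (1.0 - s10) ** 0.1


def aggregate_areas(data: CountData, mapping: dict) -> CountData:
    """Sum counts over areas mapped into regions; totals are conserved."""
    df = data.frame.copy()
    unmapped = sorted(set(df["area"]) - set(mapping))
    if unmapped:
        raise ValueError(f"areas missing from the region mapping: {unmapped}")
    df["area"] = df["area"].map(mapping)
    agg = (
        df.groupby(["area", "gender", "age", "measure"], as_index=False)[["num", "denom"]]
        .sum()
    )
    return CountData(agg)


# ---------------------------------------------------------------------------
# CSV plumbing


def read_disease_data(path) -> CountData:
    """Read and validate count-format disease data from CSV."""
    df = pd.read_csv(path)
    try:
        return CountData(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def read_estimate_data(path) -> pd.DataFrame:
    """Read estimate-format data: agegroup_start, agegroup_end, measure, est,
    lower, upper, with optional area and gender columns."""
    df = pd.read_csv(path)
    required = ["agegroup_start", "agegroup_end", "measure", "est", "lower", "upper"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: estimate data missing columns {missing}")
    for col, default in (("area", "all"), ("gender", "all")):
        if col not in df.columns:
            df[col] = default
    bad = ~df["measure"].isin(MEASURES)
    if bad.any():
        raise ValueError(
            f"{path}: unknown measure at rows {df.index[bad].tolist()[:5]}"
        )
    return df


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def prepare_counts(estimates: pd.DataFrame, max_age: int | None = None) -> CountData:
    """Full preparation pipeline: estimates -> counts -> one-year counts.

    For each (area, gender, measure), every age-group estimate is
    converted to an equivalent count pair, and the group counts are then
    smoothly disaggregated to single years of age.
    """
    frames = []
    for (area, gender, measure), sub in estimates.groupby(["area", "gender", "measure"]):
        rows = []
        for _, r in sub.iterrows():
            rec = EstimateRecord(
                age_start=int(r["agegroup_start"]),
                age_end=int(r["agegroup_end"]),
                estimate=float(r["est"]),
                lower=float(r["lower"]),
                upper=float(r["upper"]),
            )
            y, n = counts_from_estimate(rec)
            rows.append((rec.age_start, rec.age_end, y, n))
        gdf = pd.DataFrame(rows, columns=["age_start", "age_end", "num", "denom"])
        yearly = disaggregate_age_groups(gdf)
        yearly["area"] = area
        yearly["gender"] = gender
        yearly["measure"] = measure
        frames.append(yearly)
    full = pd.concat(frames, ignore_index=True)
    if max_age is not None:
        full = full[full["age"] <= max_age]
    return CountData(full)
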