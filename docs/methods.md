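# Methods

## Disease process

A disease is a continuous-time, age-inhomogeneous Markov process with
three states: 1 = disease-free, 2 = disease, 3 = dead from the disease.
Mortality from other causes is excluded by construction, so state 3
counts only disease-specific deaths and diseases can be modelled
independently of one another. Transition rates — incidence `i_a`,
remission `r_a`, case fatality `f_a` — are per person-year and constant
within integer years of age on `[a, a+1)`.

The annual transition probability matrix is the matrix exponential of
the intensity matrix over unit time. Because the death row of the
intensity matrix is zero, only the 2×2 live-state block needs
exponentiating, and it has a closed form:
`expm(M) = e^τ [cosh(d) I + sinh(d)/d (M − τI)]` with `τ = tr(M)/2` and
`d² = τ² − det(M) = ((i + r − f)² + 4rf)/4 ≥ 0`. The implementation
evaluates this through `exp(τ ± d)` (both in [0, 1]) so it cannot
overflow for any rate magnitude, with a series fallback for `d → 0`.
Tests cross-check it against both `scipy.linalg.expm` and high-accuracy
ODE integration of `dP/dt = PQ` (two independent oracles).

Cohort occupancy follows `S_{a+1} = S_a P_a` from `S_0 = (1, 0, 0)`
(overridable for conditions present at birth). If the hypothetical
cohort is numerically extinct at the oldest ages (alive probability
below 1e-12), the last well-defined prevalence is carried forward and
the ages are logged, rather than producing NaN.

### Calendar-time trends

Trends cannot be estimated from single-year cross-sectional data, so
they enter as known constants: matrices `ρ_{a,y}` of the ratio of each
rate in calendar year `y` (0..100, with 100 the data year) to its
current-year value, applied as `i_{a,y} = ρ^{(i)}_{a,y} i_a` and
`f_{a,y} = ρ^{(f)}_{a,y} f_a`. Each birth cohort is then advanced
through its own calendar-specific matrices
(`S_{a,y} = S_{a−1,y−1} P_{a−1,y−1}`), and all reported outcome
probabilities refer to the data year. With all ratios equal to 1 this
reduces exactly (to machine precision) to the stationary pathway — a
tested invariant. Ratio matrices supplied at a subset of years are
completed by carrying the earliest year backward and interpolating gaps
linearly on the log-ratio scale.

## Age curves

Log rates are spline functions of age with K = 10 basis terms: an
intercept, a linear term in age scaled to [0, 1] (so the slope is the
total log-rate change across the age range, keeping slope priors such as
N(5, 5²) on a sensible scale), and K − 2 smooth terms built from a cubic
radial basis `|x − κ_j|³` on evenly spaced knots, residualised against
the linear part, orthonormalised, and rescaled to O(1) entries. Their
coefficients are exchangeable N(0, λ₀²); as λ₀ → 0 the curve collapses
to a line on the log scale (a tested property), and λ₀ carries a
Gamma(2, 1) prior so the data determine the smoothness. The precise knot
layout and orthonormalisation are this package's own construction
choices within the thin-plate family.

Each rate's basis is built **on its own informative age range**
`[a_base, A]`, not on 0..A. Below `a_base` the curve is constant at its
value at `a_base` either way, so the fitted model is identical in
substance — but a full-range basis contains coefficient directions that
act only on ages where the curve is never evaluated. Those directions
form a likelihood null space: flat at the mode with only quartic growth,
which defeats quasi-Newton optimisation and makes any quadratic
(Laplace) approximation meaningless along them. Restricting the basis
rows to the evaluated ages removes the null space entirely.

With `increasing=True` the same spline models the log *increments*:
`rate_a = Σ_{b=a_base..a} exp(s(b))`, anchored so
`rate_{a_base} = exp(s(a_base))` — nondecreasing for every coefficient
vector (a property test).

## Priors and parameterisation

Defaults: vague N(0, 100²) on single-population intercepts and slopes;
Gamma(2, 1) on each smoothness SD λ₀; hierarchical mean intercept
b₁ ~ N(0, 10²) and common slope b₂ ~ N(5, 5²); additive male offsets
N(0, 0.82²) on intercept and slope (95% prior rate-ratio interval ≈
0.2–5) and N(0, λ₀⁽ᵐᵃˡᵉ⁾²) on the nonlinear terms, with λ₀⁽ᵐᵃˡᵉ⁾ fixed
at 1 by default (it may instead be given a prior; fixing it is this
package's default resolution of a genuinely open choice).

The between-area SD λ₁ gets a gamma prior elicited from fold-ratio
beliefs: with high- and low-risk areas defined as the 2.5% and 97.5%
quantiles of the between-area distribution, the ratio of their case
fatality is `exp(2 z₀.₉₇₅ λ₁)`. A numerical search finds the gamma
(shape, scale) whose mean maps to the guessed ratio and whose 97.5%
quantile maps to the upper limit. At fixed mean the gamma's upper
quantile is *not monotone* in the shape (it vanishes as shape → 0, peaks,
then decreases to the mean): the search solves on the decreasing branch,
which is the less extreme prior, and verifies both round-trips to 1e-6.
`z₀.₉₇₅ = 1.959964` throughout.

All sampling happens on an unconstrained space: scale parameters on the
log scale (Jacobians included), and every scaled coefficient block
**non-centered** — nonlinear coefficients are `λ₀ · z` with z ~ N(0, 1),
hierarchical intercepts `b₁ + λ₁ · u` with u ~ N(0, 1). The centered
form has no joint posterior mode (the density is unbounded at the funnel
neck λ₀ → 0 when eight coefficients share one scale), so mode-based
inference requires the non-centered form; it also improves MCMC
geometry. The two forms define the same model.

Remission is either absent (r ≡ 0), a single constant rate shared across
ages and areas (as appropriate when remission data come from national
survival statistics), or a spline of age. Between-area variation in
remission is not modelled. Outcome measures absent from the data are
simply omitted from the likelihood, which supports leave-one-source-out
sensitivity analyses. Records with n = 0 contribute exactly zero; a
probability of 0 or 1 incompatible with its count yields −inf pointwise
log-likelihood, flagged in logs, never an exception.

## Inference

**Mode + normal approximation.** The mode is found by Fisher scoring:
the likelihood gradient is `Jᵀ (∂ll/∂p)` where J is the Jacobian of
record-level outcome probabilities with respect to the parameters
(central finite differences of p — first differences of well-scaled
quantities, no catastrophic cancellation), the prior gradient is
analytic, and each Newton step uses the expected-information Hessian
`Jᵀ W J + prior curvature` (W = n/(p(1−p))), positive definite by
construction, with backtracking line search. This matters: the posterior
is severely anisotropic (intercept and slope are nearly collinear when
only part of the age range is informative), and both finite-difference
Hessians and gradient-free quasi-Newton methods stall or produce saddle
artifacts here.

The covariance is the inverse expected information at the mode
(diagonal-jitter policy, logged, if a conditional block is not positive
definite). Draws are taken by default from the normal **conditional on
the scale hyperparameters at their modal values**: the map from the
remaining coordinates to log rates is then linear, so rate intervals are
log-normal. Joint normal draws over (log λ₀, z) would pass through the
λ₀·z product, inflating rate intervals well beyond the true posterior's;
conditioning removes this at the cost of ignoring smoothness-parameter
uncertainty — the same conditioning used to stabilise MCMC in hard
cases. Plain joint draws and draws importance-corrected to the exact
posterior (Pareto-smoothed weights, systematic resampling) remain
available via the `adjust` argument.

**Posterior sampling.** Full MCMC uses the affine-invariant ensemble
sampler (emcee), with walkers initialised from unadjusted normal-
approximation draws so the ensemble starts dispersed across the
posterior bulk; the first half of each run is burn-in. Walkers are
grouped into pseudo-chains for split-R̂ and bulk-ESS diagnostics
(arviz); R̂ > 1.01 warns rather than fails. Runs are exactly
reproducible given a seed. On the reference synthetic fixture the two
engines' 95% case-fatality intervals overlap by ≈ 90% (intersection over
union) and mode-finding is two orders of magnitude faster than sampling.

Initialisation: spline coefficients zero except intercepts at crude
log-rate estimates (mortality/prevalence for case fatality, incidence
proportions for incidence), scale hyperparameters at prior means, with
jittered restarts on a non-finite start.

## Model checking

**Conflict p-values.** Each observed count is compared against the
model's synthesis of the other evidence: the count alone gives a
conjugate Beta(y + 0.5, n − y + 0.5) posterior for its probability, and
`q = Pr(p < p_full)` is computed by averaging the Beta CDF over the
posterior draws of the modelled probability (Rao-Blackwellised — less
Monte Carlo noise than draw-vs-draw comparison; the summarisation choice
is this package's). The two-sided conflict p-value is `2 min(q, 1 − q)`.
Under self-consistent simulation the p < 0.05 rate is close to nominal
(tested within [3%, 7%] over 2000 records). With n = 0 the prior alone
is used.

**LOO ELPD.** Pointwise expected log predictive density via
Pareto-smoothed importance sampling over the (draws × observations)
log-likelihood matrix built by the engines; weight smoothing is
delegated to `arviz.psislw`. A single draw, or fully degenerate draws,
falls back to the plain log pointwise density, flagged. Model comparison
is the difference of totals; tests confirm it selects the generating
gender structure (additive vs area-specific) under both truths.

## Data preparation

**Estimate + interval → counts.** Published (estimate, 95% interval)
triples are inverted to the (y, n) whose Beta(y + 0.5, n − y + 0.5)
interval best matches the published bounds in squared error, with
y = round(estimate·n) — a Jeffreys-style interval-matching target chosen
because only "approximately equivalent" counts are required; acceptance
is tolerance-based (interval width reproduced within 10%).

**Age-group disaggregation.** Group counts are split into one-year
counts by a penalised composite-link Poisson model: smooth log yearly
means with a second-order difference penalty, penalty weight chosen by
AIC over a 10⁰..10⁶ grid, IWLS fitting. Yearly values are then rescaled
so every group total is conserved **exactly** and rounded by
largest-remainder apportionment; numerators and denominators are
disaggregated consistently, with a conserving repair step if rounding
ever pushes a numerator above its denominator. Terminal open-ended
groups should be closed at the oldest modelled age before input.

**Remission from survival.** `r = 1 − (1 − s₁₀)^(1/10)` inverts the
10-year survival identity `s₁₀ = 1 − (1 − r)^10`.

## Synthetic data

The generator produces datasets with exactly the generative structure
the model assumes, from true curves in the fitted spline family:
case fatality rising smoothly from ≈ 0.026/yr at age 50 to ≈ 0.14/yr at
100 (constant below 50), incidence from ≈ 0.001/yr at 30 to ≈ 0.009/yr
with a plateau at the oldest ages — magnitudes typical of a common
chronic disease. Hierarchical scenarios draw area intercepts from
N(b₁, λ₁²) with λ₁ = 0.3 over 4 areas by default; gendered scenarios add
a male offset (+0.5 intercept, +0.3 slope), either common to areas or
area-specific (±0.3–0.7) for the interaction variant. Default
denominators are ≈ 50 000 per age for incidence and mortality and
≈ 2 000 for prevalence, decaying to 10% above age 90, emulating
aggregate administrative data where the oldest ages are weakly informed.

What passing recovery tests does and does not show: the generator draws
exact binomial counts from the model's own outcome probabilities, so
recovery and calibration results demonstrate internal correctness —
identifiability, unbiasedness and interval calibration under a correctly
specified model — not robustness to the ways real burden data violate
it (non-binomial extraction error in published estimates, populations
mixed across sources, unmodelled secular trends, misspecified age
shapes). The conflict p-value and ELPD machinery exist precisely to
probe those violations on real data.

Recovery test summaries: accuracy is assessed as the mean relative error
of the posterior median over ages with true prevalence above 1%
(observed 2–5% per replicate at the default denominators; a max-over-ages
criterion would be dominated by single-age binomial noise of ±5–8%), and
interval calibration as pooled 95% coverage over 50 replicates, required
to lie in [88%, 99%] (observed ≈ 92%).

## Problem sizes

Default test and acceptance runs use A = 100 (ages 0..100), K = 10 basis
terms, one to four areas, 50 recovery replicates, MCMC with ~2 n + 2
walkers for several thousand iterations, and 400–1200 approximation
draws — sizes chosen so the full statistical suite exercises every
pathway in a few minutes on one CPU.

## Known limitations

- Case fatality independent of time since onset (Markov assumption);
  often violated soon after onset of acute-event diseases.
- Other-cause mortality excluded by construction; no competing-risks
  coupling between diseases, no combined-disease states.
- No spatial correlation between areas and no covariates beyond age,
  gender, area; trends are fixed inputs, never estimated.
- The conditional normal approximation ignores smoothness-hyperparameter
  uncertainty; when that matters, use the sampling engine.
- The ensemble sampler needs many iterations on strongly correlated
  high-dimensional posteriors (hierarchical + gender models); the mode
  engine is the practical default there, as full MCMC was for the
  hardest configurations in the motivating applications.
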