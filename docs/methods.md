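# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `relmediate`, together with what the synthetic-data
generator does and does not emulate.

## Hazard decomposition and lifetables

The all-cause rate is decomposed as `h = h* + λ`: a parameter-free expected
(background) rate `h*` looked up in a population lifetable, plus an excess
rate `λ` attributable to the disease. Lifetables follow the standard
ratetable convention: rates constant within 1-year age bands crossed with
1-year calendar periods, optionally stratified (for instance by deprivation
group). Attained age and attained calendar year advance together with
follow-up time, so a subject's cumulative expected hazard is the exact
integral of a piecewise-constant path, splitting at every band boundary;
the implementation evaluates it as a piecewise-linear function, which is
exact, and `S* = exp(−cumhaz)`.

Conventions (defaults, with rationale):

- ages above the table cap (99 by default in the synthetic tables) clamp to
  the cap row rather than erroring — registry lifetables end in an open age
  band; years outside coverage clamp to the nearest covered year;
- fractional ages at diagnosis are allowed and banded by `floor`;
- an unstratified lifetable is treated as shared across exposure groups.
  The AC1 all-cause contrast (below) is then degenerate, and the package
  refuses to compute it unless the caller passes an explicit
  `allow_unstratified=True` — degrade loudly, not silently.

## Spline basis

Restricted (natural) cubic splines use the truncated-power form with
λ-weights: for knots `k₁ < … < k_K`, column 1 is `x` and column
`j ∈ 2..K−1` is

    v_j(x) = [(x−k_j)₊³ − λ_j (x−k₁)₊³ − (1−λ_j)(x−k_K)₊³] / (k_K−k₁)²,
    λ_j = (k_K−k_j)/(k_K−k₁),

linear outside the boundary knots and zero at/below `k₁`. The same closed
form supplies analytic first derivatives, so hazards and cumulative hazards
are always mutually consistent. Default knot placement is at equally spaced
centiles of the uncensored log event times (boundary knots at min/max); the
package defaults are 5 df for the baseline, 3 df for time-dependent
effects, and 3 df for age — knot placement itself is a convention of
flexible-parametric practice, not a reproduced quantity. An optional
orthogonalization (column centring + QR-based affine map, fixed at spec
creation) improves optimizer conditioning; because the map is affine and
invertible, predictions are invariant, and a test asserts this to 1e−10.

## Excess-hazard model

On the log cumulative excess hazard scale,

    η(t; z) = s₀(ln t) + z'β + Σ_j z_j s_j(ln t),

with `Λ_E = exp(η)`, `R = exp(−Λ_E)` and
`λ(t) = (1/t) (∂η/∂ ln t) exp(η)`. The excess hazard is deliberately not
constrained nonnegative (standard behaviour of models on this scale). The
log likelihood, dropping the `ln S*` terms constant in β, is

    ℓ(β) = Σᵢ [ dᵢ ln(h*ᵢ(tᵢ) + λᵢ(tᵢ)) − Λ_{E,i}(tᵢ) ],

with `h*ᵢ` evaluated once per record at the attained age and year at exit
(it is parameter-free, so only its value at the event time matters). If a
trial β makes the total hazard at an event time nonpositive, the log is
continued linearly below a floor of 1e−10 — `ln ε + (x−ε)/ε` — keeping the
objective finite and smooth so the optimizer can recover.

Fitting maximizes ℓ with its analytic gradient: L-BFGS-B followed by Newton
polishing on a central-difference Hessian with Levenberg damping.
Internally the design matrix is rescaled to unit root-mean-square columns —
a pure reparameterization (coefficients and covariance are mapped back
exactly) that keeps the Hessian well conditioned; without it a few percent
of small-sample fits stall just above tolerance. Convergence requires the
original-scale gradient max-norm below 1e−6 (at most 200 quasi-Newton
iterations plus 40 polish steps); failure raises with diagnostics. The
coefficient covariance is the inverse negative Hessian at the optimum.
Rank-deficient designs are detected up front via QR and reported with the
names of the collinear columns. Time origin is diagnosis; no delayed entry,
cure fractions, frailty or interval censoring.

## Mediator model

A multinomial logit for the mediator given exposure and confounders (age
through its own 3-df spline with knots from the pooled age distribution —
independent of the survival model's age basis), fitted by maximum
likelihood via statsmodels. The reference level is the first declared level
(all estimands are invariant to this). Predictions are softmaxes computed
from the stored coefficients, so bootstrap-drawn coefficient vectors reuse
the identical code path; rows sum to one within 1e−12 by construction.

## Standardization and estimands

Every estimand derives from

    ξ(y, x; t) = (1/N) Σᵢ Σₘ R(t | X=y, Z2=zᵢ, M=m) P(M=m | X=x, Z2=zᵢ),

standardized over the empirical confounder distribution of the declared
reference population (the whole sample by default; the exposed subset for
avoidable-deaths questions). Net-scale natural effects are
`NDE = ξ(1,0) − ξ(0,0)`, `NIE = ξ(1,1) − ξ(1,0)`, `TCE = NDE + NIE`
(additivity holds to machine precision because ξ(1,0) cancels exactly), and
`PM = NIE/TCE`. PM is reported only where `|TCE|` exceeds a tolerance
(default 1e−4 on the probability scale) — the ratio is meaningless near a
null total effect — and is flagged, not silently NaN-propagated.

All-cause constructions multiply each individual term by an expected
survival factor before averaging: AC1 sets the lifetable stratum to the
exposure of the relative-survival factor (requires an exposure-stratified
lifetable); AC2 uses each individual's observed-exposure `S*` in both
contrast terms, so AC2 differences are attributable to the cancer alone.
The default reporting scale is the probability of death, `1 − survival`
(signs flip consistently; PM is unchanged); the survival scale is available
by flag. The default time grid is 0.05–5 years in steps of 0.05: the model
lives on `ln t`, so `t = 0` is never evaluated (survival there is 1 by
definition).

A `StandardizationEngine` precomputes all parameter-free design pieces (the
counterfactual design matrices per (y, m) and the `S*` matrices), reducing
each bootstrap replicate to a handful of matrix products. The engine and
the direct path are verified identical to 1e−12, and both are verified
against explicit nested loops on small fixtures.

## Avoidable deaths

Among the exposed subset (size `N_{X=1}`), expected deaths by time `t`
under a regime `(y, x)` are

    D(t) = N* · (1 − (1/N_{X=1}) Σᵢ S*ᵢ(t) Σₘ R(t|y, zᵢ, m) P(m|x, zᵢ)),

with `S*` always the exposed group's own (interventions act on cancer
mortality only). Scenario 1 shifts both the mediator distribution and
relative survival to the unexposed (`y=0, x=0`); scenario 2 shifts the
mediator distribution only (`y=1, x=0`). `AD = D₁ − D_scenario`, and the
scenario-1 total partitions exactly into the scenario-2 component plus a
relative-survival residual. `N*` is user-supplied; the package also
computes candidates from the data (exposed count in the most recent
diagnosis year; mean annual exposed count; per-1,000) and records which was
used. AD is exactly linear in `N*`.

## Parametric bootstrap

Coefficients of the two models are drawn independently from
`MVN(estimate, covariance)` — the models are fitted separately, so no
cross-covariance exists. Covariances are factorized by eigendecomposition
with negative eigenvalues clipped at zero (numerical Hessians can be
indefinite at round-off level, and occasionally a near-unidentified
direction appears in small samples); any clip beyond round-off warns.
Intervals are `point ± 1.96 · SD` of the replicates by default (k = 500),
with 2.5/97.5 percentiles available; the reported point estimate is always
the original fit, never the bootstrap mean. Replicates that fail are
recorded and excluded; more than 5% failures is a hard error. All draws are
bit-reproducible given the seed.

## Synthetic data and its truth

The generator emulates a two-group registry: exposure prevalence 0.424,
female prevalence 0.465, age truncated-normal (mean 69, SD 13, bounds
18–99), diagnosis years 2011–2013, a 4-level stage mediator from a
multinomial logit (marginal mix ≈ 15/29/27/29%, shifting toward the most
advanced level with exposure, age and male sex), a Weibull excess hazard
(`λ₀ = 0.02`, `κ = 0.8` at the reference profile; strong stage gradients,
a modest direct exposure effect of 0.15 on the log scale, 0.02/year for
age), and Gompertz background mortality per sex discretized into 1-year
bands (rate over `[a, a+1)` equal to the band-average hazard), 40% higher
for the exposed stratum. Administrative censoring is at 5.5 years. These
defaults were chosen once to be epidemiologically plausible for a
colon-cancer-like setting and are not calibrated to any published numbers.

Other-cause deaths are simulated by inversion through exactly the same
discretized rates that the emitted lifetable contains, so the
"appropriate expected rates" assumption holds by construction; a
`lifetable_misspecification` factor can scale the emitted table (but not
the simulation) for robustness experiments.

`true_surfaces` evaluates every estimand in closed form: exact Weibull
relative survival and exact softmax mediator probabilities, summed exactly
over sex, mediator level and (for AC2) exposure, and integrated over age by
trapezoidal quadrature on 2,001 nodes by default (integration error on the
order of 1e−7; a Monte-Carlo cross-check with 10⁶ covariate draws agrees to
3 decimals). The truth's `θ(t|X=x)` is defined as `ξ(x,x)` — the marginal
relative survival with the mediator at its natural distribution under the
set exposure.

What the generator does *not* emulate — hence what passing tests do not
establish about real registries: informative censoring, dependent competing
risks, lifetable insufficiency (confounders missing from `Z1`), missing
stage data, period effects in background mortality, or intermediate
confounders affected by exposure. The estimators inherit the method's
assumptions (consistency, conditional exchangeability for both causes, no
interference, cross-world independence); none of these are testable here.

## Problem sizes used in the test suite

End-to-end recovery fits n = 20,000 (one dataset, seed 0); the bootstrap
coverage study uses 200 datasets of n = 2,000 with k = 200 replicates; the
Weibull recovery uses n = 5,000. At n = 20,000 and study-scale disparities
the sampling SD of the 3-year TCE is ≈ 0.007 on the probability scale, and
the relative sampling SD of the avoidable-deaths estimates is ≈ 11%
(scenario 1) and ≈ 26% (scenario 2) — the mediator-shift contrast is
intrinsically noisy, as the wide intervals reported for such quantities in
applied analyses also show. Recovery checks at fixed seeds should be read
with those magnitudes in mind; consistency was verified separately at
n = 100,000, where all recovery errors fall to ≤ 0.003.

## Known limitations

- No multiple imputation for a partially missing mediator; complete cases
  only.
- No time-varying exposures or confounders, no delayed entry, no
  M-estimation (sandwich) standard errors — the bootstrap is the only
  uncertainty method.
- AC1 contrasts require an exposure-stratified lifetable; the escape hatch
  for unstratified tables changes the estimand (background mortality equal
  across arms) and is therefore opt-in.
- The excess hazard is unconstrained; in sparse strata predictions can
  yield locally negative excess hazards, which is visible in `excess_hazard`
  rather than masked.
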