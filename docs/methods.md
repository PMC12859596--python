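# Methods

This note documents the statistical model, the priors, the sampler, the
synthetic-data generator and the numerical conventions used throughout
`hurdlemap`, together with the design choices that were genuinely open
and the reasons for the ones taken.

## The hurdle model

Small-area counts of a rare event are heavily zero-inflated simply
because the expected count per area-year is near or below one. The
package therefore separates *whether* any event occurs from *how many*
occur: a Bernoulli gate with probability `pi`, and a zero-truncated
Poisson (ZTP) with rate `mu` for the positive counts,

    P(y = 0)         = 1 - pi
    P(y = k), k >= 1 = pi * mu^k e^(-mu) / (k! (1 - e^(-mu))).

When `pi = 1 - e^(-mu)` the hurdle law collapses exactly to an ordinary
Poisson — a nesting identity the test-suite checks numerically, and a
useful way to see that the gate models *extra* structure in the zeros
rather than replacing the Poisson zeros.

The count component uses the indirectly standardised expected count as
an offset, so `exp` of the remaining predictor is a relative risk (RR)
against an average area with the same age-sex structure. The offset is
deliberately excluded from the gate: the gate's predictor is a
log-odds, and pushing a log-expectation into it would conflate
population size with the propensity for any event; the shared random
effects already let the gate borrow the count component's structure.
The gate receives the count component's spatial, temporal and
interaction effects multiplied by free scalar sharing coefficients
(`delta_s`, `delta_t`, `delta_st`) — the canonical joint-model
construction when two likelihood components share latent fields. Each
component keeps its own intercept and covariate coefficients.

## Latent structure and priors

* **Spatial (BYM2)**: `b = (sqrt(phi) u + sqrt(1 - phi) v) / sqrt(tau_b)`
  with `u` an intrinsic CAR (ICAR) field on the area graph scaled so the
  geometric mean of its constrained marginal variances is one, `v` iid
  standard normal, `phi in [0, 1]` the mixing parameter and `tau_b` the
  marginal precision. Sum-to-zero is imposed on `u` within each
  connected component; isolated areas carry only unstructured variance.
* **Temporal**: a first-order random walk `gamma` (scaled like the
  ICAR, sum-to-zero) plus an exchangeable year effect `phi_t`, with
  precisions `tau_gamma`, `tau_t`.
* **Space-time interaction**: exchangeable effects `psi_it` (the
  simplest interaction type: independent across cells), precision
  `tau_st`.
* **Hyperpriors**: every precision carries the penalised-complexity
  (PC) prior defined by `P(1/sqrt(tau) > 1) = 0.01` (an exponential
  with rate `-log(0.01)` on the sd scale). The BYM2 mixing parameter
  carries its spectrum-dependent PC prior with the statement
  `P(phi < 0.5) = 0.5`, evaluated on a grid from a dense
  eigendecomposition of the scaled structured covariance; if the
  statement is unattainable for a given graph spectrum the prior falls
  back to the base-rate limit (uniform on the KL distance scale).
* **Fixed effects**: Gaussian `N(0, 10^2)` on intercepts and
  coefficients — weakly informative on log/logit scales given
  standardised covariates. Log sharing scales carry `N(0, 1)`.

All structure flags and prior constants live in `ModelSpec`; components
can be switched off individually (e.g. a fixed-effects-only model for
oracle checks, or temporal off for single-year data).

## Standardisation

Reference rates pool deaths and person-years over *all* areas and years
of the panel, per age-band and sex; expected counts are
`E(i,t) = sum_strata population * rate`. Pooling internally makes
`sum E = sum deaths` exactly (a conservation identity tested to 1e-9
relative error) and assumes stratum rates constant over the study
period. Area-years with zero population in every stratum would produce
`E = 0`; they are rejected at validation rather than dropped, because a
silently incomplete space-time grid corrupts every downstream index.

## Sampler

Inference is a blocked adaptive Metropolis-within-Gibbs scheme on the
non-centred parameterisation (standardised fields, precisions entering
the predictors as `1/sqrt(tau)`):

* `(alpha_p, beta_p)` and `(alpha_b, beta_b)` update as blocks with
  Gaussian random-walk proposals shaped by running posterior standard
  deviations (Welford) and a scalar step adapted to ~0.23 acceptance.
* Latent fields update site-wise with per-site steps adapted to ~0.44
  acceptance. Sites with mutually independent full conditionals move
  simultaneously: the iid fields in one vectorised sweep; the ICAR and
  random-walk fields over the colour classes of a greedy graph
  colouring, so no two neighbours move together.
* Hyperparameters use scalar random walks on log (precisions, sharing
  scales) or logit (`phi`) scales.
* Three non-obvious moves are load-bearing for mixing:
  1. a *spatial-confounding exchange* that shifts `(alpha_p, beta_p)`
     while compensating through the unstructured spatial component so
     the count predictor is invariant — without it, spatially smooth
     covariates and the BYM2 field trade off so slowly that coefficient
     chains stall;
  2. an *interweaving rescale* for each precision, proposing
     `tau -> c*tau` with the standardised field rescaled by `sqrt(c)`
     so the composite effect (and hence the likelihood) is invariant;
  3. a *sharing-ridge move* proposing `tau -> c*tau` jointly with
     `delta -> delta*sqrt(c)`, which leaves the gate contribution
     invariant and walks the long ridge between a field's scale and its
     sharing coefficient.
  Each is a valid Metropolis move on the same target; the prior-only
  sampling test (quadrature oracle) and the simulation-based
  calibration test exercise all of them.
* Sum-to-zero constraints are enforced by re-centring the structured
  fields once per sweep (per graph component; over years for the random
  walk), after which all caches are rebuilt from the parameter state.
* Chains run sequentially on independent substreams of one integer
  seed; runs are bit-reproducible. Default run: 4 chains x 5000
  iterations, half warmup. Adaptation happens only during warmup.

Convergence is reported as split R-hat and effective sample size
(via ArviZ) over intercepts, coefficients, hyperparameters and a seeded
subset of latent effects, with an overall pass flag at R-hat < 1.05 and
a hard-failure flag (degenerate chains or R-hat > 1.2) that the
pipeline surfaces through its exit status. The sharing coefficients and
the interaction precision are the slowest-mixing quantities; reduced
runs that are fine for coefficient estimates can still show R-hat above
1.05 on those hyperparameters.

## Summaries

* RR functionals: year `exp(gamma_t + phi_t)`; area
  `exp(x'beta_p + b)`; area-year adds `psi`; region-year is the
  expected-count-weighted mean of area-year RR draws over a region's
  areas (weights respect the population structure). The area-level RR
  includes the covariate contribution — covariates are part of what
  makes an area's risk differ from average — and the sum-to-zero
  constraints centre the comparisons.
* Summaries are posterior medians and equal-tailed credible intervals
  with the standard linear-interpolation quantile rule. For per-SD
  percent changes, quantiles are taken on the coefficient scale and
  transformed by `100(exp(beta) - 1)` (monotone, so the interval is the
  same CrI; the median of two draws {0, log 1.5} is 22.47%, not 25%).
* Exceedance is the fraction of draws with RR strictly greater than 1,
  banded low [0, 0.2], medium (0.2, 0.8], high (0.8, 1] — both
  boundaries closed on the right.
* Variance decomposition: per draw, the variance over all (area, year)
  units of each component's contribution divided by the variance of the
  total non-offset, non-intercept predictor. Components may covary, so
  shares need not sum to 100; draws with zero total variance are
  excluded (error if more than half would be).
* Profile table: units ranked by posterior-median area-year RR
  (ties broken by stable unit order), split into 100 near-equal bins
  (sizes differ by at most one), reporting each bin's mean standardised
  covariate scores.

## Synthetic data generator

The generator emulates the structure of a national small-area mortality
study: a rook-adjacency lattice stands in for the real adjacency graph
(the model consumes topology, not cartography); 8 age bands x 2 sexes
per area-year with stratum populations uniform on [300, 1000] (areas of
roughly 5,000-15,000 residents); stratum baseline rates in a
suicide-like regime (~1e-4 deaths per person-year overall, male rates
about 3x female, a mid-life peak), giving expected counts near one per
area-year and ~50% zero cells; seven (by default) standardised
covariates from a proper Leroux-form CAR field with autocorrelation 0.5
(so that covariates are themselves spatially smooth, the regime in
which spatial confounding actually bites); and counts drawn from the
hurdle model itself, with default effect scales `sd_spatial = 0.3`,
`phi = 0.6`, `sd_gamma = 0.1`, `sd_t = 0.05`, `sd_st = 0.1`, sharing
scales 1 and gate intercept 0 (`pi = 0.5` at baseline). Simulated
area-year totals are spread over strata by a multinomial proportional
to stratum expected deaths, which keeps the standardisation
self-consistent by construction.

What the generator does **not** emulate: realistic population pyramids
or migration, time-varying covariates, reporting/registration delay,
irregular adjacency with enclaves, and covariate measurement error.
Passing tests on this synthetic world therefore demonstrate the
correctness of the machinery and recoverability of effects under the
model's own assumptions — not robustness to the misspecifications real
mortality data contain.

## Numerical conventions

* Eigendecompositions of the ICAR/RW structures are dense; eigenvalues
  below `max(eig) * 1e-9` count as null space. This is exact and cheap
  up to a few thousand areas, which is the intended scale.
* Standardisation of covariate columns uses the population (ddof = 0)
  standard deviation, both in the generator and on load; files whose
  columns are not standardised are re-standardised with a logged
  warning, and constant columns are an error.
* The per-cell log-likelihood is computed from the linear predictors
  with softplus/expm1 identities; for `mu < 1e-10` the ZTP
  normalisation `log(1 - e^(-mu))` is replaced by its asymptote
  `log mu` so that underflow cannot produce spurious `+inf`, and
  overflow of `exp(eta)` propagates to `-inf` (rejection).
* Graph edges are stored sorted; area identifiers are opaque strings
  mapped to indices by sorted order; all output tables are written with
  a fixed float format so reruns are byte-identical.
* Test and example run lengths are scaled to the problem sizes used
  (hundreds to a thousand area-years); they are stated in each test and
  were chosen so the slowest-mixing hyperparameters reach usable
  diagnostics without multi-hour runs.

## Identifiability of the gate's covariate effects

With free sharing scales, the gate's covariate coefficients `beta_b`
are only weakly identified when covariates are spatially smooth: the
BYM2 field can absorb the covariate pattern at low prior cost (smooth
patterns sit in the cheap part of the ICAR spectrum), the sharing
coefficient `delta_s` rescales that absorbed pattern for the gate, and
the count component's coefficients counter-shift — a ridge along which
both likelihood components are exactly invariant and only the Gaussian
field priors resist. The sampler includes an exchange move that walks
this ridge directly, so long runs reveal the genuinely diffuse
posterior of `beta_b` (and slow-looking R-hat on gate coefficients at
short run lengths) instead of silently under-reporting it. None of the
headline summaries (relative risks, per-SD percent changes, variance
shares, profiles) uses `beta_b`; they are built from the count
component, which the positive counts pin well. When gate-specific
covariate effects are themselves of interest, fix the sharing scales
(`share_scales_free=False`) or report the shared (count-side) effects.

## Known limitations

* Only Type-I (exchangeable) space-time interaction is implemented;
  structured interactions would need Kronecker precision machinery.
* The sharing construction is scalar per field; component-specific
  random effects (rather than scaled copies) are not supported.
* Dense spectral preprocessing limits the practical graph size to a few
  thousand areas on desktop memory.
* The exceedance bands and RR functionals are reporting conventions;
  alternative choices (e.g. excluding covariates from the area-level
  RR) change interpretation, not fit.
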