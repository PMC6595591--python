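# Methods

## The problem

Hospital report cards invite "league tables" that rank providers on a
quality indicator (death, readmission, long length of stay, ...).  Whether
such a ranking is meaningful depends on the indicator's **rankability**

    rho = tau^2 / (tau^2 + median_j(s_j^2)),

the share of the observed between-hospital variation that reflects true
differences rather than chance.  Here `tau^2` is the between-hospital
variance estimated by a random-intercept (logistic or cumulative-logit)
model, and `s_j` is the Wald standard error of hospital *j*'s effect in the
companion fixed-effects model; the median is taken over the hospitals
retained by the fixed fit.  Values above 0.7 are conventionally "high",
below 0.5 "low".  The related latent-variable intraclass correlation is
`ICC = tau^2 / (tau^2 + pi^2/3)`.

Many real indicators have low-to-moderate rankability.  This package
implements a Monte Carlo study of one remedy: pooling three
severity-ordered binary indicators into a five-level ordinal composite
(level 5 when the most severe indicator is present regardless of the
others; 4 when the two milder ones co-occur; 3 and 2 for each milder one
alone; 1 for none) and asking when the composite out-ranks its components.

## Data-generating model

Patients `i = 1..n` are nested in hospitals `j = 1..K` (volume fixed across
hospitals by design, to isolate the phenomena of interest from volume
variation).  Each patient has one standard-normal risk score `x_ij` that
enters all three indicators:

    logit Pr(Y_kij = 1) = a_kj + slope_k * x_ij,   k = 1, 2, 3,

with hospital intercept triples `(a_1j, a_2j, a_3j)` drawn from a
multivariate normal with means `alpha0_k`, SDs `tau_k`, and a single
exchangeable correlation `r` (positive definite iff `r > -1/2`).  Given the
intercepts and the risk score, the three Bernoulli draws are conditionally
independent; all the between-indicator dependence is carried by the
correlated hospital effects and the shared risk score.  Defaults mirror
conditions typical of provider profiling: marginal prevalences
(0.05, 0.10, 0.25) — most severe rarest — slopes (-0.25, 0.50, 1.0), 100
hospitals of 500 or 1000 patients.

## Calibration

Scenario targets are prevalences and component rankabilities, so the
generator solves for `(alpha0_k, tau_k)`:

* **Intercepts** by bisection on the marginal prevalence
  `E[expit(L)]`, `L ~ N(alpha0, tau^2 + slope^2)`, computed with 80-node
  Gauss–Hermite quadrature (absolute error < 1e-6 vs a 10x denser rule over
  the parameter ranges used; tolerance of the root 1e-5 in prevalence).
  The function is strictly increasing in `alpha0`, so a sign-changing
  bracket always exists.
* **Random-effect SDs** by grid search (default grid 0.05–1.5, step 0.05):
  at each visited node the intercept is re-calibrated, replicate datasets
  are simulated (default 10 per node) and the mean estimated binary
  rankability is compared with the target.  Because the response is
  monotone in `tau`, the grid is scanned by bisection, the final bracket is
  subdivided once (at large volumes the response jumps by more than 0.1
  between adjacent coarse nodes), and the evaluated node means are pooled
  by isotonic regression before the final selection.  The pooling matters:
  selecting whichever node's noisy mean lands nearest the target is a
  winner's-curse rule whose chosen `tau` systematically overshoots the
  target rankability once fresh data are simulated.  A calibration whose
  best pooled gap exceeds 0.1 raises an error carrying the evaluated curve.
* An **analytic variant** replaces the simulated response by its
  large-sample expectation, `rho(tau) = tau^2 / (tau^2 + median E[s^2])`
  with `E[s^2]` the inverse per-hospital Fisher information
  `n * E_x[p(1-p)]` evaluated at the quantiles of the intercept
  distribution, inverted by root finding.  It involves no simulation or
  fitting and is used where a fit-free calibration is required (e.g. the
  prevalence reproduction run); it runs in milliseconds and lands within
  a few hundredths of the simulated response.

Because the correlation does not affect the marginal distribution of any
single indicator, one calibration per (target, prevalence, slope, volume)
combination is shared across correlations and replicates.

## Model fitting

* **Fixed-effects binary logistic** (`logit Pr = alpha_j [+ beta x]`, no
  global intercept, one effect per hospital): Newton iterations exploiting
  the arrow structure of the information matrix (diagonal over hospital
  effects plus one slope row/column), O(N) per iteration; Wald SEs from the
  same structure in closed form.  Hospitals with 0% or 100% events are
  excluded and reported — their effects diverge.
* **Fixed-effects proportional odds** (`Pr(Y<=l) = expit(c_l - h_j -
  beta x)`): exact Newton on the full gradient/Hessian with the sum-to-zero
  constraint `sum h_j = 0` imposed through a bordered system; the
  constraint identifies the hospital effects against the thresholds while
  treating all K hospitals symmetrically, so every hospital contributes an
  `s_j`.  Standard errors come from the bordered information inverse.
  Hospitals entirely in one extreme level are excluded.
* **Random-intercept binary and ordinal models**: marginal maximum
  likelihood with adaptive Gauss–Hermite quadrature — per hospital, the
  integrand is re-centred at the posterior mode (inner vectorised Newton)
  and scaled by the posterior curvature; 15 nodes by default (1 node is the
  Laplace approximation; 15 vs 25 nodes moves fixture log-likelihoods by
  < 1e-4).  The optimiser is L-BFGS-B over `(alpha0, beta, tau)` (binary)
  or `(thresholds, beta, tau)` (ordinal, thresholds parameterised as a
  first cut plus log-increments so they stay ordered), with gradients from
  Fisher's identity (posterior expectations of the complete-data score,
  evaluated at the quadrature nodes).  `tau` is estimated on the SD scale
  with the boundary at zero permitted (an internal floor of 1e-4 keeps the
  quadrature well-defined; estimates at the floor are reported as
  `tau2_hat = 0`).  Non-convergence is flagged on the result, never
  silently defaulted.

Fitted log-likelihoods agree with dense-trapezoid integration oracles to
~1e-13 on toy data, and the two-level collapse of either ordinal fitter
reproduces its binary counterpart to 1e-6 in log-likelihood.

## Study pipeline

Study A crosses 13 ICC values (0–0.24) with four intercepts and three
slopes (156 scenarios); Study B crosses eight random-effect correlations
with two volumes and three target-rankability triples (48 scenarios), plus
an equal-prevalence variant with all prevalences 0.10.  The three triples —
(0.25, 0.35, 0.45), (0.35, 0.45, 0.55), (0.45, 0.55, 0.65) — span the low
(< 0.5) and moderate (0.5–0.7) bands and are configurable.  Per scenario,
replicates are simulated and all four indicators' rankabilities estimated
with paired fixed/random fits; replicates in which any required fit failed
to converge are dropped from the scenario means and counted.  A scenario's
composite "beats all" when its mean rankability exceeds each component's
mean.  Aggregations report the dominance fraction per correlation level and
an OLS meta-regression (classical SEs) of the composite's mean rankability
on the three component means, a volume indicator (1000 vs 500) and the
correlation.

Seeding: every replicate's generator stream is derived as
`SeedSequence(master_seed, spawn_key=(scenario_index, replicate))`, and
calibration streams get disjoint spawn keys, so any replicate is
reproducible in isolation and results are bit-identical for any worker
count and identical CSV output for a given (scenario, seed).

## Problem sizes used in tests and reproduction runs

The full study (48 scenarios x 100 replicates of 100x500–1000, plus the
Study-A factorial) is what the `ranklab run-study` CLI executes.  The test
suite and the reproduction script use reduced profiles chosen as the
package's own defaults for routine verification:

* prevalence reproduction: all 48 scenarios at design volumes, 5 replicate
  datasets each, analytic calibration (fit-free);
* dominance checks: 50 hospitals x 200 patients, 10 replicates per
  scenario, correlations {0.5, 0.75, 0.9} (and {0.75, 0.9} for the
  equal-prevalence variant), simulation-based calibration with 25
  replicates per grid node;
* Study-A ordering: 5 ICC values x 2 intercepts, 20 replicates at 50x200;
* variance recovery: 50 replicates at the full 100x500.

At 10 replicates the scenario means carry Monte Carlo noise of roughly
0.02; the corr = 0.5 dominance margins are about +0.05..+0.07, so the
reduced dominance checks are informative but not immune to rare flips at
extreme seeds.

## What the generator does and does not emulate

It reproduces the features the rankability question turns on: clustering
with controllable between-hospital variance, severity-ordered prevalences,
within-hospital correlation of indicators, and a shared patient risk
factor.  It does not emulate varying hospital volumes, multi-covariate
case mix, non-normal random effects, random slopes, or indicators defined
on different patient populations — so passing tests say nothing about
robustness to those features of real report-card data.  Alternative
composites (e.g. counts of positive indicators) are out of scope.

## Known limitations

* The proportional-odds assumption is deliberately violated when
  components are weakly correlated — that is the mechanism under study —
  so the ordinal `tau^2` is then a compromise across cut-points, not a
  structural parameter.
* The analytic calibration ignores the small downward finite-sample bias
  of `tau2_hat` and the slope-estimation contribution to `s_j`; at K = 50
  it sits within a few hundredths of the simulated response.
* Fixed-effects exclusions (zero-event hospitals) slightly censor the
  `s_j` distribution at very low prevalence and volume; the median is
  robust to the few exclusions observed at the study's sizes.
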