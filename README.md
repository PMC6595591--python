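# ranklab

Can pooling several binary hospital-quality indicators into one ordinal
composite make hospital rankings more reliable?  `ranklab` implements the
statistical machinery to answer that question by simulation: the
**rankability** statistic, the calibrated clustered-data generator, the
four mixed/fixed model fits rankability needs, and a replicated Monte Carlo
scenario pipeline.  It is aimed at biostatisticians and health-services
researchers working on provider profiling.

## The statistic

For a binary indicator `Y_ij` (patient *i*, hospital *j*) with risk score
`x_ij`, two companion models are fitted:

* random intercepts: `logit Pr(Y_ij = 1) = beta x_ij + a_j`,
  `a_j ~ N(alpha_0, tau^2)` — marginal ML by adaptive Gauss–Hermite
  quadrature;
* fixed effects: one effect per hospital with Wald standard error `s_j`.

Rankability is

```
rho = tau^2 / (tau^2 + median_j(s_j^2))
```

— the proportion of between-hospital variation not due to chance
(`> 0.7` high, `< 0.5` low; the latent-variable ICC is
`tau^2 / (tau^2 + pi^2/3)`).  For a five-level ordinal composite the same
construction uses random- and fixed-effects proportional-odds models.  The
composite maps three severity-ordered binary indicators (Y1 most severe and
rarest, Y3 mildest and most frequent) to level 5 if Y1 occurred, 4 if Y2
and Y3, 3 if Y2 only, 2 if Y3 only, 1 otherwise.

The simulator draws hospital intercept triples from a multivariate normal
with an exchangeable within-hospital correlation and calibrates intercepts
(bisection on a quadrature marginal prevalence) and random-effect SDs
(monotone grid search against estimated rankability, or a closed-form
expected-information variant) to hit target prevalences and component
rankabilities.  See `docs/methods.md` for details.

## Worked example

Simulate one strongly-correlated composite scenario and estimate the
composite's rankability:

```
$ cat scenario.yaml
study: B
re_correlation: 0.9
n_hospitals: 20
n_per_hospital: 100

$ ranklab simulate --scenario scenario.yaml --seed 4 --out data.csv
wrote 2000 rows to data.csv

$ ranklab rankability --data data.csv --indicator ordinal
{
  "rho": 0.7110396477300479,
  "tau2_hat": 0.09816060294135076,
  "median_s2": 0.039891618555330466,
  "n_hospitals_used": 20,
  "indicator": "ordinal",
  "converged": true
}
```

The estimated between-hospital variance (0.098) is about 2.5 times the
median squared standard error of the hospital effects (0.040), so about
71% of the observed variation in the composite reflects true hospital
differences — "high" rankability by the usual 0.7 convention.

A small scenario study over three correlation levels shows the study's
central finding — the composite only dominates its components when they
are strongly correlated within hospitals:

```
$ ranklab run-study --study B --config grid.yaml --reps 2 --seed 5 \
      --calibration-method analytic --out out/
$ ranklab summarize --results out/scenarios.csv
re_correlation  n_scenarios  frac_composite_beats_all  frac_composite_below_best
           0.0            3                  0.000000                   1.000000
           0.5            3                  1.000000                   0.000000
           0.9            3                  1.000000                   0.000000
           all            9                  0.666667                   0.333333
```

At correlation 0, the composite ranks worse than its best component in
every scenario (pooling weakly-related indicators violates the
proportional-odds assumption and averages opposing hospital effects); at
correlations 0.5 and 0.9 it beats all three components everywhere.

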