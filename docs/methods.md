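# Methods

## The analysis chain

`agediff` implements the complete computational chain from trial-level
binary-choice response times to a mediation answer: do slower peripheral
processes (non-decision time) account for age differences in intelligence
test scores?

1. **Diffusion model.** Each participant x task block of (RT, accuracy)
   pairs is described by a two-boundary Wiener process: evidence starts at
   `z = a/2` (accuracy coding, no response bias), accumulates with drift `v`
   and unit within-trial scaling `s = 1`, and a response is emitted when it
   reaches 0 (error) or `a` (correct). Observed RT adds a non-decision
   component drawn uniformly from `[t0 - st0/2, t0 + st0/2]`. Inter-trial
   variability of drift and start point are fixed at zero; only
   `(v, a, t0, st0)` are free.
2. **Screening.** Trials faster than 300 ms are dropped (strict
   inequality), then a single-pass per-block fence at `[Q1 - 3 IQR,
   Q3 + 3 IQR]` (type-7 quantiles). After fitting, blocks failing a
   parametric-bootstrap adequacy check are masked, then blocks whose mean
   RT or accuracy falls 3 IQRs outside that task's quartiles, and finally
   whole participants whose squared Mahalanobis distance over all 93
   features (v, a, t0, st0, mean RT per task, three content-domain scores)
   exceeds the chi-squared critical value at p = .001.
3. **Composites.** Per-task values are z-standardized over the
   post-exclusion sample and averaged per participant, over all 18 tasks
   and per content domain, for v, a, t0 and mean log RT. Rows missing some
   tasks average the available ones; alpha/PCA use listwise deletion.
4. **Mediation.** All variables standardized to unit variance;
   predictor->mediator paths from simple OLS, mediator->outcome and direct
   paths from the multiple regression of the outcome on predictor plus all
   mediators. The least-squares identity `c = c' + sum(a_i b_i)` then holds
   exactly, and the proportion mediated is `100 (1 - c'/c)`. Uncertainty
   for each indirect effect comes from a case-resampling bootstrap with
   percentile intervals at 99.5%, matching the strict alpha of .005 used
   for all significance tests.

## First-passage numerics

The defective density at a boundary uses the standard pair of series
representations — the small-time image expansion and the large-time
eigenfunction expansion — with per-evaluation term counts chosen from the
usual truncation bounds at a 1e-7 target, and the cheaper branch selected
each call. The defective CDF uses an exact image sum of inverse-Gaussian
terms (evaluated in log space so the `exp(-2vc)` factors cannot overflow)
for normalized time `t/a^2 < 0.2` and the integrated eigenfunction series
otherwise. The st0-averaged observed-RT density is computed exactly as a
scaled CDF difference `[F(t - t0 + st0/2) - F(t - t0 - st0/2)] / st0`; the
observed-RT CDF averages the decision CDF over the uniform window with
11-node Gauss-Legendre quadrature. Densities below 1e-10 are floored so a
stray trial cannot produce an infinite objective.

Simulation is exact inverse-CDF sampling: boundary by its absorption
probability, decision time by bisection on the conditional CDF, plus a
uniform non-decision draw. The bootstrap adequacy check amortizes this with
a 96-point conditional-quantile grid per boundary (draws landing in the
outer cells fall back to exact bisection).

## Estimation

Nelder-Mead on a transformed space: raw `v`, `log a`, the logit of the
*lower window edge* `t0 - st0/2` relative to the fastest trial, and
`log st0`. Only the lower edge is constrained below `min(rt)`; the window
may extend past the fastest trial, which matters because `min(rt)`
converges to `t0 - st0/2` from above as trials accumulate. Starting values
come from EZ-style moment equations (edge-corrected accuracy, correct-RT
mean and variance); `fit_ml` defaults to 5 multistarts (EZ plus four
jittered). The pipeline uses an adaptive variant — extra starts run only
when the first solution fails to converge or sits on the edge of the
feasible region (at most 2 extras) — because across ~2200 blocks per cohort
the EZ start is reliable and the flat multistart spends most of its time
reconfirming the same optimum. Convergence tolerances are `xatol 1e-3` on
the transformed scale and `fatol 5e-3` nats; at these settings simulate-
and-refit at 10,000 trials recovers all four parameters within 5% relative
error, and 100-trial blocks give true-vs-fitted correlations above .9.

## Fit adequacy check

The adequacy criterion is a parametric bootstrap: simulate `n_sim`
(default 200; 100 in the pipeline) datasets of the observed size at the
fitted parameters; the discrepancy statistic is the category-frequency-
weighted sum of squared differences between empirical and model-implied RT
deciles for both response categories, plus the squared accuracy gap. A fit
is inadequate when the observed discrepancy exceeds the `1 - q` simulated
quantile (`q = 0.05`). Simulated datasets are *not* refitted; the check is
therefore calibrated against parameter-conditional rather than estimation-
inflated discrepancy, a deliberate trade of a small calibration error for a
~100x cost reduction. Under the null the empirical rejection rate sits at
the nominal `q` within binomial error (see the test suite).

## Synthetic cohort

The generator emulates the study design: 123 adults, ages uniform on
18-62, 18 tasks (figural/numeric/verbal x fast/slow x 3), 100 trials per
block, and a 12-subtest intelligence battery (6 processing capacity, 3
psychometric speed, 3 memory; 4 subtests per content domain).

Latent structure (standardized loadings): age -> non-decision time 0.55,
age -> boundary separation 0.45, age -> drift 0 (optionally hump-shaped
with a peak near age 30), residual t0-boundary correlation 0.3, drift
independent of age. Per-task true parameters map each participant's latent
through a moment-matched lognormal onto the task's mean/SD from a published
battery-scale table (fast tasks v ~ 2.7-5.0, a ~ 0.9-1.5, t0 ~ 0.36-0.53 s;
slow tasks v ~ 0.5-1.2, a ~ 2.9-4.0, t0 ~ 0.84-1.64 s); the lognormal keeps
slow-task t0 positive even where the table SD approaches the mean, where an
additive map would need heavy truncation. Any two tasks share a
configurable `cross_task_r = 0.5` in their true values. `st0 = 0.15 t0`.
0.5% of trials are replaced by fast contaminants uniform on 0.15-0.30 s so
the 300 ms floor has work to do.

Intelligence subtests load `lambda_v * v* - lambda_t0 * t0*` plus a domain
factor (0.25) and unique noise: processing capacity (.50, .35), psychometric
speed (.25, .60), memory (.40, .40). These values were fixed by variance
arithmetic to land near the empirical magnitude pattern (g-t0 about -.6,
g-v about +.6, age-g about -.4) and to give the Model 2 non-decision-time
indirect effect enough power (~0.9) for a 99.5% CI to exclude zero at
n = 123. Boundary separation deliberately does not enter the scores, so its
age-linked composite shows a predictor path but a null indirect effect.

What the generator does **not** emulate: task-specific age effects (all age
signal flows through the three general latents, so composite reliabilities
come out around .85-.95, higher than typical empirical values near .7-.85);
item-level response processes for the intelligence battery; practice,
fatigue, or session effects; non-uniform age distributions. Passing the
end-to-end tests therefore shows the chain recovers the structure it
assumes, not that the structure is true of any real sample.

## Problem sizes in the test suite

The acceptance tests run the full chain at the default design (n = 123, 18
tasks, 100 trials) across 8 seeds with 1000 bootstrap resamples per model,
requiring the qualitative pattern in at least 80% of seeds; recovery uses
100 blocks of 100 trials plus 20 replications at 1000 trials; bootstrap
coverage uses 500 outer replications of 1000 resamples. These sizes are the
package's chosen defaults for a single-workstation run; all are plain
parameters of the tests and scale up without code changes.

## Numerical and design choices

- Quantiles everywhere are linear-interpolation (type 7).
- `s = 1` scaling throughout, stored on the parameter object; a consistent
  rescaling of (s, v, a) leaves the likelihood invariant (tested).
- "Faster than 300 ms" is strict; ties at the floor are kept.
- The Mahalanobis screen uses the classical covariance. At the replication
  design (93 features, ~123 participants, incomplete rows skipped) that
  matrix is singular or near-singular, so the pipeline opts into the
  pseudo-inverse metric explicitly (`mahalanobis_pseudo_inverse = True`);
  distances in that metric live in the rank-deficient subspace and the
  fixed chi-squared cutoff is then conservative. With ample complete rows
  the classical inverse is used and the cutoff is exact.
- Proportion mediated above 100% (direct effect of opposite sign) is
  reported and flagged as suppression rather than clipped.
- Bootstrap resamples with a degenerate (constant) variable are redrawn and
  counted; percentile intervals throughout.
- An exactly collinear mediator pair (|r| > 0.999) is an error naming the
  pair, since the path split is unidentified.

## Known limitations

- The adequacy check's no-refit bootstrap slightly mis-states the null
  when parameters are poorly determined (very few error trials).
- PCA general-factor loadings are upward-biased relative to factor-analytic
  loadings; the decomposition is a principal-component approximation, not a
  latent-variable model.
- Composite reliabilities in the synthetic cohort exceed typical empirical
  values (see above); alpha values reported on synthetic data are
  generator properties, not empirical claims.
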