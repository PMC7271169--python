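# Methods

`efpath` re-implements, as a tested and reusable pipeline, an analysis chain
common in cognitive-aging research: trial-level executive-function (EF) task
data are reduced to participant-level scores, combined into
Unity-and-Diversity EF components, and entered as outcomes of a parallel
multiple-mediator path model testing whether frontoparietal brain measures
mediate age differences in EF. Because datasets of this kind are typically
available only on request, the package ships a first-class synthetic-data
module that generates every input with known ground truth.

## Task scoring

**Switch cost.** Mean RT on switch trials minus mean RT on repeat trials,
restricted to mixed-task blocks with informative cues. Only correct trials
enter: errors trigger feedback and postpone the following trial, so their
RTs measure a different process. Units: milliseconds; positive values mean
slower switching.

**2-back d′.** Equal-variance signal-detection sensitivity, d′ = Φ⁻¹(H) −
Φ⁻¹(F), with H the "same" rate on targets and F the "same" rate on
nontargets. Omitted responses count as misses (targets) and correct
rejections (nontargets). Extreme rates are replaced by 1/(2N) and 1 − 1/(2N)
(N = trials in that cell) so the quantiles stay finite; this is the standard
correction and matters only for near-ceiling participants. The pipeline
carries the *negated* d′ so that all three task measures are oriented
worse-is-higher.

**SSRT.** Stop-signal reaction time by the median method: median correct
go-trial RT minus median delivered stop-signal delay (SSD). The median
method is the default because it is robust to the constant-SSRT assumption;
an integration-method estimator is provided as a clearly labeled
alternative, not used anywhere by default. Medians with even counts are the
mean of the two central order statistics.

## EF components

Following the Unity-and-Diversity composite/residual arithmetic (no latent
variables): the three task measures are z-scored across the sample (sample
SD, n−1); the **common EF** component is their per-participant mean; each
**specific** component (shifting, updating, inhibition) is the OLS residual
of one task's z-score on the other two plus an intercept. Residuals are
orthogonal to their regressors by construction (asserted to 1e-10 in tests).
Specific components are re-z-scored before correlation or mediation so every
modeled variable is unit variance. Residualization uses the negated d′
throughout for one consistent orientation; a `raw` orientation toggle exists
in the pipeline configuration. Missing task scores cause listwise exclusion
with a logged count.

Correlations are Pearson, optionally partialled on covariates by
residualizing both variables on an intercept plus the covariate matrix;
p-values are two-tailed from t with n − 2 − k degrees of freedom. Both plain
and covariate-adjusted modes are exposed because published scatterplots of
such data are typically unadjusted while the modeling is adjusted.

## Graph metrics

Participation coefficient PC_i = 1 − Σ_s (k_is/k_i)² and within-module
degree z-score WMD_i = (k_i^within − μ_m)/σ_m, in their canonical weighted
(Guimerà–Amaral) forms. Conventions, stated because they differ between
implementations:

* negative connectivity weights are zeroed before any degree computation
  (default policy; a proportional-threshold option exists but is off);
* σ_m is the population (n-denominator) SD within the module — the same
  convention as bctpy's `module_degree_zscore`;
* isolated nodes get PC = 0; modules of size 1 or zero spread get WMD = 0;
* the module partition is an input; no community detection is performed.

The two scalar mediators `pc_fp`/`wmd_fp` are unweighted means over a
declared frontoparietal node list. By default metrics are computed on the
full graph and then averaged over that list (`scope="full"`); computing them
on the frontoparietal subgraph (`scope="subgraph"`) is supported, since with
modules defined a priori either reading of "restrict to frontoparietal
nodes" is defensible.

## Parallel mediation with BC bootstrap

The model is the saturated linear path system with exposure x (age), J = 8
simultaneous mediators (four regional gray-matter volumes, two SLF FA
values, `pc_fp`, `wmd_fp`), outcome y (one EF component) and covariates
(gender, education, BDI-II) in every equation. Because the system is
saturated, OLS reproduces the maximum-likelihood point estimates, and the
decomposition c = c′ + Σ_j a_j b_j is an exact algebraic identity on the
fitted sample (asserted to 1e-10). All variables are z-scored once on the
listwise-complete sample (default), so reported paths are standardized
coefficients; standardization once — rather than inside every bootstrap
replicate — matches the convention of standardizing before model entry.

Confidence intervals are bias-corrected (BC, no acceleration) percentile
intervals from a cases bootstrap: participants are resampled with
replacement n times per replicate (B = 5000 by default), all path equations
are refit per replicate (vectorized batched normal-equation solves), and for
each effect θ the interval endpoints are the type-7 empirical quantiles of
the bootstrap draws at levels Φ(2z0 + z_{α/2}), Φ(2z0 + z_{1−α/2}) with
z0 = Φ⁻¹(P*(θ* < θ̂)). Ties enter the proportion at midrank; a proportion of
0 or 1 is clipped to 1/(2B) from the boundary; all-equal draws collapse the
interval to a point. Singular replicates are redrawn (logged) and more than
1% of them is an error suggesting a larger sample. Reported p-values invert
the interval: p = 2·min(Φ(w − 2z0), 1 − Φ(w − 2z0)) with w the normal
quantile of the draws' midrank proportion below zero — the α at which a BC
endpoint touches zero. An effect is declared significant iff its interval
excludes zero; a boundary exactly at zero is not significant.

The study-level driver fits one model per EF outcome (common, shifting-,
updating-specific — three models) and screens the eight covariate-adjusted
age–mediator correlations at the Bonferroni per-test level 0.05/8 = 0.00625.

### Calibration behavior worth knowing

The test suite measures the frequentist behavior of the BC interval for a
specific indirect effect:

* with a genuine effect (a = b = 0.4, n = 200, B = 1000), 95% intervals
  cover the true product at the nominal rate (93–97% over 500 replicates);
* under a *complete* null (a = b = 0), the product test is strongly
  conservative — the rejection rate is near 1%, not 5% — because the
  bootstrap distribution of a product of two near-zero estimates
  concentrates at zero. This is a known property of product-of-coefficients
  tests, not an implementation artifact; the suite asserts the
  conservativeness explicitly. Under a partial null (mediators age-linked,
  b = 0) rejection is near nominal, mildly liberal at n ≈ 126.

## Synthetic data

The generators emulate the study design the pipeline targets:

* **Stop-signal sessions**: independent horse race between an ex-Gaussian go
  process (defaults μ = 500, σ = 50, τ = 150 ms) and a normal stop process
  (mean 240, sd 30 ms; sd = 0 gives the constant-SSRT regime). Five blocks
  of 100 go + 40 stop trials; each stop trial draws one of two interleaved
  1-up/1-down staircases (starts 150/350 ms, ±50 ms, clamped to [0, 800] ms)
  chosen uniformly at random; stop success iff G > SSD + S. Go omissions and
  errors are injected independently of RT (a simplification; real lapses
  correlate with slow responses). The adaptive design holds group-mean stop
  success at or slightly above 50% — slightly above because both staircases
  start below the convergence point.
* **Task-switching sessions**: per mixed block, a balanced 35/35
  switch/repeat sequence is shuffle-rejected until no same-kind run exceeds
  4, giving an exact 50% switch share by construction; RT = base + cost ·
  1[switch] + Gaussian noise; informative and noninformative cue blocks and
  single-task blocks are emitted so the scorer's restriction logic is
  exercised.
* **2-back sessions**: 3 blocks × 21 trials (positions on a 9-cell grid,
  target rate 0.3 from trial 3 onward), responses from the equal-variance
  SDT model with a set true d′ (default 1.8, the level implied by ~80%
  accuracy) and criterion.
* **Cohorts**: age uniform on 20–78 years; each mediator is a_j·z(age) plus
  noise completing unit variance, with default a_j for the six structural
  measures spread over −0.40…−0.65 (the published range for age–brain
  correlations in such samples) and 0 for the two network measures; the
  outcome `ef_outcome` follows c′·z(age) + Σ b_j m_j with its residual
  completing unit variance, so construction slopes equal population
  standardized coefficients. Default truth plants one nonzero b path (left
  frontal gray matter). Three task-level true scores load λ = 0.85 on the
  outcome and are mapped to natural units (switch cost 78.69 ± 112.83 ms,
  SSRT 241.28 ± 113.29 ms, d′ ≈ 1.8 ± 0.6) to drive the trial generators
  end-to-end. Covariates: gender Bernoulli(0.5); education normal 14 ± 2.5 y
  clipped to [6, 22]; BDI-II normal 5 ± 4 clipped to [0, 14) per the usual
  depression-screening exclusion. `exact_residuals=True` orthogonalizes
  every residual in-sample against its equation's design, which makes
  unstandardized OLS reproduce the ground-truth ledger to machine precision
  (useful for exactness tests; a literal zero-noise system would make the
  mediators collinear with age and the model unidentified).
* **Connectivity**: block-structured symmetric zero-diagonal matrices with
  within/between-module weights plus symmetric Gaussian noise; negatives are
  left in deliberately to exercise the zeroing policy.

What the generators do **not** emulate: practice/fatigue and post-error
slowing, RT–lapse dependence, non-Gaussian mediator distributions,
measurement error in the brain measures, realistic BOLD-derived connectivity
spectra, or the recruitment/exclusion process. Passing tests therefore
demonstrate correctness of the estimators and their calibration under the
stated generative model, not robustness to every feature of real data.

## Problem sizes and determinism

Every generator and the bootstrap are seed-deterministic; identical seeds
and inputs give byte-identical output files (the run manifest records a
configuration hash). The statistical suites use the design sizes stated
above (200 simulated subjects for stop-signal properties; 1000 blocks for
sequence shares; 200 cohorts of n = 2000 for point-estimate bias; 500
replicates at B = 1000 for interval calibration); these sizes put
Monte-Carlo error comfortably inside the asserted bands while keeping a
full test run in minutes.

## Known limitations

* Only the cases bootstrap is implemented (no residual bootstrap, no BCa
  acceleration, no robust/heteroscedastic SEs, no multiple imputation).
* Listwise deletion is the only missing-data strategy, as in the modeling
  tradition this follows.
* The FC ingestion path consumes dense matrices as given; edge definition
  (correlation type, Fisher z, thresholding beyond the negative-weight
  policy) is the caller's responsibility.
* The integration-method SSRT is a convenience alternative and is less
  thoroughly exercised than the median method.
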