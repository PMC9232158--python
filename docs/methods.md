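# Methods

## The estimands

`dispmed` decomposes the disparity in a binary adverse outcome Y between an
exposed group (X = 1, low education in the stroke application) and an
unexposed group, given baseline confounders C, into components mediated by
two named blocks of binary mediators: block A ("risk factors") and block B
("prevention drugs"), M = (M_A, M_B).

All effects are *interventional disparity* quantities: they ask how the
disparity would change if the mediator distribution of the exposed were
shifted to that of unexposed patients with the same confounder values.
Unlike natural direct/indirect effects, they are well defined without
assuming the causal ordering among the mediators or the absence of
unobserved mediator–mediator confounding.

Write r(x_out, source) for the mean of the outcome-model prediction at
exposure level `x_out`, with mediator vectors drawn from `source`, averaged
over the confounder distribution of a reference population (default: the
exposed). Mediator sources are

- `joint(x_m)` — the full mediator vector drawn from its joint distribution
  at exposure x_m, represented by sequential logistic models
  M_j | X, C, M_1..M_{j-1} in schema order (block A then block B);
- `indep(x_a, x_b)` — every block-A mediator drawn from its marginal model
  M_j | X = x_a, C and every block-B mediator from its marginal model at
  x_b, all mutually independently.

The six reported quantities, on the absolute-risk-difference scale in
percentage points:

| quantity | definition |
|---|---|
| ATA    | r(1, joint(1)) − r(0, joint(0)) |
| DE     | r(1, joint(0)) − r(0, joint(0)) |
| IE_all | r(1, joint(1)) − r(1, joint(0)) |
| IE_A   | r(1, indep(1,1)) − r(1, indep(0,1)) |
| IE_B   | r(1, indep(0,1)) − r(1, indep(0,0)) |
| IE_dep | IE_all − IE_A − IE_B |

ATA = DE + IE_all and IE_all = IE_A + IE_B + IE_dep hold exactly by
construction because each regime mean is computed once and shared between
contrasts. ATA is model based (both terms come from the fitted models)
rather than a raw adjusted difference, so the decomposition closes.

**Anchoring.** IE_A and IE_B are order dependent through the `indep`
anchors: the default varies block A first while holding block B at the
exposed level (the telescoping path (1,1) → (0,1) → (0,0)). The
complementary anchoring (`anchor="b_first"`) varies block B first. Swapping
the block labels under one anchoring reproduces the values of the other;
the sum IE_A + IE_B is anchoring invariant. This is exposed rather than
hidden because no convention is canonical.

**IE_dep.** The dependence component is exactly zero when the mediators are
conditionally independent given (X, C) and the sequential and marginal
models agree. Within-block dependence alone (with independent blocks) does
not force IE_dep = 0, because the `indep` source breaks *all* mediator
dependence, not only the between-block part; with a non-additive outcome
model a small IE_dep can then remain. The test suite checks the
machine-zero property in the conditionally independent case.

## Estimation

1. Fit by maximum likelihood: the outcome model Y | X, M, C; sequential
   mediator models M_j | X, C, M_1..M_{j-1}; marginal mediator models
   M_j | X, C. The default specification includes all 2-way interactions
   between predictor units plus squared age; a main-effects variant supports
   robustness comparisons. Odds-ratio association tables use main effects +
   age² only, because a table of single-coefficient odds ratios is
   incompatible with exposure-by-covariate interactions.
2. Build the standardization population: confounder vectors of all rows in
   the reference group (default X = 1), equal weights.
3. Compute the seven distinct regime means either by
   - **enumeration** over all 2^J mediator patterns (exact given the fitted
     models; the joint weights grow by prefix doubling through the
     sequential factorization), or
   - **Monte Carlo** with K simulated mediator vectors per population row
     per regime (default K = 500). The same uniform draws are reused across
     regimes (common random numbers), which keeps the decomposition
     identities exact and shrinks the variance of the contrasts. The
     per-regime Monte-Carlo error is O(1/√K), verified empirically.
4. Inference: nonparametric bootstrap (default B = 1000), full refit of all
   models per resample. SE = SD over replicates; 95% CI = estimate ±
   1.96·SE (normal construction, matching the symmetric intervals of
   standard reporting; percentile intervals optional);
   p = 2·Φ(−|estimate|/SE), with the convention p = 1 when SE = 0 and the
   estimate is 0. Replicates with non-convergent models or degenerate
   resamples are dropped and counted; runs with > 5% failures are flagged.
   The seed schedule spawns one substream per replicate, so results are
   reproducible and invariant to the worker count.

## Numerical choices

- Logistic fits use Newton–Raphson with step halving; convergence requires
  a relative deviance change below 1e−10 and a small gradient. Perfect
  separation is reported through a `converged=False` flag (the engine
  refuses to proceed unless a ridge fallback, default 1e−6 in the
  imputation cycle, is enabled). Rank-deficient designs raise an error
  naming the collinear columns.
- Continuous confounders are centered and scaled before squaring; year of
  stroke enters as indicator columns against 2012. Linear predictors are
  clipped at ±35 before exponentiation.
- The two display age bins "75–84" and "84+" overlap at 84 in the registry
  convention; they are resolved as [75, 85) and [85, ∞). Bins are display
  only: analysis models always use continuous age (and age²).

## The synthetic registry generator

The generator draws C = (sex, age, year), then X | C, then M_1..M_9
sequentially, then Y | X, M, C — exactly the model family the engine fits,
so parameter recovery is a meaningful end-to-end test. Age is truncated
normal (mean 75.3 y, SD 12 y, range 18–100; the registry reports only the
mean, the shape is a package choice); sex and year follow the registry
margins.

`rikslike_preset()` fixes the slope coefficients as follows: exposure
coefficients in the mediator models and exposure/mediator coefficients in
the outcome model equal the published adjusted log odds ratios
(e.g. exposure→smoking log 1.37, atrial fibrillation→outcome log 1.90, ADL
dependency→outcome log 2.88); confounder slopes and cross-mediator
dependence are fixed clinically plausible values chosen once (age raises
atrial fibrillation, ADL dependency and antihypertensive use; risk factors
drive drug prescription, which creates the between-block dependence;
atrial fibrillation strongly indicates anticoagulants). Intercepts are then
*calibrated deterministically*: working forward through the factorization,
each intercept is solved by root finding so that the implied marginal
prevalence — computed exactly on a 1-year age grid by enumerating the joint
distribution — hits the published marginal (low education 43.5%, lowered
consciousness 11.7%, atrial fibrillation 28.9%, antihypertensives 66.5%,
etc.). Accuracy is limited only by the age discretization (well below 0.1
percentage points).

Published marginals and pairwise odds ratios do not identify a full joint
distribution; the preset is one documented member of the compatible family.
The generated data are complete, balanced in time, and free of real-data
features such as measurement error, informative missingness, repeat
admissions and unmeasured confounding — passing tests therefore validate
the *estimation machinery*, not substantive conclusions about stroke care.

`true_effects()` computes the six estimands exactly from the generating
coefficients by enumerating the confounder grid, both exposure levels and
all 2^9 mediator patterns; the `indep` marginals are exact marginalizations
of the sequential factorization. It is the oracle for the recovery and
coverage tests.

Missingness injection is MCAR or MAR (logit shift by a fully observed
driver). The registry-like rates are smoking 9.5%, ADL dependency 3%, 0.33%
on the other exposure/outcome/mediator columns — chosen so the any-variable
missing fraction is 14.8% as published — with the administrative
confounders fully observed.

## Imputation

Single stochastic chained-equations imputation (default 10 burn-in cycles):
initialize missing cells from observed marginals; visit incomplete
variables in order of increasing missingness (ties by schema order); refit
each conditional model on the currently completed data and redraw the
missing cells (binary: Bernoulli at the predicted probability; continuous:
normal around the prediction with the residual SD; categorical: softmax
over per-level logistic scores). Conditionals use main effects only — the
imputation is a sensitivity analysis and plain conditionals are much more
stable inside the cycle. Observed cells are never modified. Multiple
imputation with pooling is deliberately out of scope.

## Validation scales

The validation suite runs the full published design at reduced size so it
completes on a single CPU in minutes; tolerances are unchanged:

- generator calibration: n = 100,000, 3 binomial SEs;
- parameter recovery: 50 replicates at n = 20,000 (enumerate mode), each
  effect's mean within 3 Monte-Carlo SEs of the exact truth;
- bootstrap coverage: 50 simulated registries at n = 2,500 with B = 50,
  the 95% CI for IE_all covering the truth in 95% ± 5 pp of runs;
- imputation sensitivity: n = 20,000, registry-like MCAR rates, B = 40
  bootstrap SEs, agreement within 3 SEs;
- Monte-Carlo convergence: K ∈ {10, 100, 1000}, 40 repetitions, log-log
  slope −0.5 ± 0.15.

## Known limitations

- The marginal mediator models are logistic fits to marginals that are not
  exactly logistic when mediators are dependent; IE_A/IE_B therefore carry
  a (small) projection approximation absent from IE_all, DE and ATA.
- Wald-type bootstrap intervals assume approximate normality of the
  estimator; percentile intervals are available but BCa is not.
- Rows are treated as independent admissions; repeat admissions of one
  patient are not modelled.
- No sensitivity analysis for unmeasured mediator–outcome confounding.
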