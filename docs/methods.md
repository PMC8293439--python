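# Methods

## Generating model

The simulator instantiates a sampling account of the positive manifold.
Persons have i.i.d. standard-normal abilities on a fixed pool of
elementary processes; nothing in the generator correlates processes
within or between persons. "Standardized multivariate normal with
identity covariance" is implemented as independent univariate draws per
cell, which is mathematically identical and avoids building a 200 x 200
covariance. Column order follows the taxonomy declaration (fluid,
verbal, spatial, EA; EA sub-pools inhibition, updating, shifting,
unspecified, common), so sampling vectors index columns
deterministically.

Sampling vectors are properties of (test, item) pairs — all persons
share an item's vectors — and are redrawn fresh in every Monte-Carlo
iteration along with abilities, difficulties and responses (a
`redraw_design_per_iteration=False` switch holds one design fixed
across iterations). All-zero vectors are legitimate draws and are kept:
for an EF common pool of 10 processes at p = 0.12, an item has
0.88^10 ≈ 0.28 probability of sampling none. Resampling such items
would inflate the expected per-item process counts above
pool_size x p (6, 14, 2.8, 1.2 under the defaults), so instead the
degenerate items carry a constant theta of zero that the z-scoring rule
maps to z = 0 for everyone; the item then contributes
logistic(-b_g) * logistic(z_s - b_s)-type terms rather than being
discarded.

Broad-ability tests pair their own 50-process domain block with the
full 50-process EA block; EF tests pair their 10-process EA sub-pool
with the 10 common EA processes. The common pool is what makes EF tests
partly process-impure and is the only source of covariance among them.

## Response model

Aggregate thetas are z-scored across persons within each (test, item)
cell so that they live on the same scale as the Normal(0, sd)
difficulties. The sample-SD convention (n - 1 denominator) is used; at
n = 1000 the population-SD alternative changes nothing visible, but the
convention is fixed here for reproducibility. Cells with zero
cross-person variance standardize to 0 by rule.

The item response function is a product of logistic terms, one per
domain: compensatory within a domain (only the summed theta enters) and
non-compensatory across domains (the product caps at the weakest
factor). Discriminations default to 1. Item difficulties b_g and b_s
are drawn independently per item — the generator imposes no within-item
correlation between the general and specific difficulty, since none is
specified — with sd 1.0 for broad tests and 0.05 for EF tests; the
tight EF spread encodes the relative stability of performance on
executive tasks. Binary responses are independent Bernoulli draws from
the probability array and are summed into 0-100 number-correct scores.

## Covariance-structure engine

Models are parameterized in RAM form (directed-coefficient matrix A,
symmetric matrix S, filter F) with implied covariance
F (I-A)^-1 S (I-A)^-T F^T. The engine minimizes the normal-theory ML
discrepancy F_ML with an analytic gradient (chain rule through the RAM
matrices) using L-BFGS-B; convergence requires the optimizer's success
flag or a max-gradient below 1e-6, with up to five jittered restarts
otherwise, and nonconvergence is flagged on the fit object rather than
silenced. Start values are anchored to the sample covariance through
marker loadings. The test statistic is chi-square = (N - 1) F_ML, with
the sample covariance computed with the N - 1 denominator; this pairing
reproduces the published RMSEA arithmetic exactly.

Identification uses the marker-variable rule (first loading per latent
fixed to 1). The fully standardized solution is computed from the
implied joint covariance of observed and latent variables and is
invariant to the identification chosen (verified in tests against a
unit-variance identification). Negative variance estimates (Heywood
cases) are permitted and logged as warnings, not constrained.

Fit indices: CFI against the independence baseline (free variances,
zero covariances — the universal convention), RMSEA =
sqrt(max(chi2 - df, 0) / (df (N-1))) with a 90% CI from inverting the
noncentral chi-square CDF in the noncentrality parameter (bounds
clamped at zero when no root exists), and SRMR over all unique
standardized residuals including the diagonal. RMSEA is reported as
not-applicable when df = 0.

Regression-method factor scores use weights Sigma^-1 Cov(observed,
latent) from the fitted model applied to centered scores; they have
mean zero by construction.

## Fitted models

Model 1 is the standard three-factor higher-order CFA (9 tests, df =
24). Model 2 adds the three EF scores as exogenous manifest predictors
of g with covariances fixed to zero (df = 51), mirroring the
orthogonality of the simulated EA sub-pools; EF variances stay free.
The correlation-matrix mode fits latent inhibition/updating/shifting
factors predicting either a latent g (with its own indicators) or a
manifest composite. EF factor covariances are fixed to zero by default:
that choice — not free correlations — reproduces the degrees of freedom
of the reanalysis models this mode is shaped after (51 for a 12-
indicator battery, 33 for 10 indicators with a composite criterion, 41
for 11 indicators), as direct parameter counting confirms. A
`ef_covariances: free` option relaxes it. Correlation matrices are
treated as covariances of standardized variables with the supplied N.

## Commonality analysis

The criterion for the simulation-study decomposition is the g factor
score from the fitted Model 1 (regression method), regressed on the
three EF test scores; the decomposition uses the seven subset R²
values, which is algebraically identical to the six-entry-orders
procedure. Components always sum exactly to the full-model R² (asserted
to 1e-10). Negative shared components (suppression) are reported as-is
with a warning, never truncated — standard commonality-analysis
behavior. The squared standardized Model 2 paths provide the SEM-side
counterpart of the unique components and are reported in the study
summary; the two differ by design, because the SEM treats the EF
measures as orthogonal while the factor-score regression sees their
common-pool covariance. For correlation-matrix input the decomposition
is computed at the latent level, from the implied EF-factor
correlations and EF-g validities of a free-correlation fit, via
R²(subset) = r' R^-1 r.

## Monte-Carlo design and seeds

A study is `n_iterations` (default 200) independent replications.
Iteration i derives its seeds from
`SeedSequence(master_seed, spawn_key=(i,))` split into four named
substreams (abilities, sampling, difficulties, responses), so any
iteration is re-runnable in isolation and the whole study is
byte-reproducible from (config, master seed). Nonconverged iterations
are excluded from summary means and counted; a summary with more than
5% failures is flagged unreliable. The summary's commonality
decomposition defaults to the first iteration, with an option to
average across iterations.

The acceptance script runs the full 200-iteration default design
(1000 persons, 200 processes, 12 tests x 100 items), the package's own
standard problem size; a complete study takes on the order of a minute
or two on one CPU, the two SEM fits dominating each ~0.3 s iteration.

## What the generator does and does not emulate

The synthetic battery realizes an idealized scenario: tasks are nearly
process-pure (EF tests touch only their own sub-pool plus a small
common pool), there is no measurement error beyond binomial response
noise, no guessing or slipping, no person-level dependence between
processes, and no non-normal abilities. Passing tests therefore show
that the sampling mechanism *can* produce a well-fitting higher-order g
structure and orthogonal EF predictors of g — not that real batteries
behave this way; real tasks are less pure and noisier, which is exactly
what the correlation-matrix mode lets one examine against published
data.

## Known limitations

* ML estimation only: no robust (mean-adjusted) or weighted-least-
  squares estimators, no missing-data likelihood, no modification
  indices or bootstrap standard errors.
* Commonality is restricted to exactly three predictors (the design of
  interest); no dominance analysis.
* No estimation of person abilities from responses (no IRT
  calibration); the IRT model is generative only.
* The Model 1 mean chi-square over 200 iterations runs ~1-2 units above
  its published counterpart while every other mean statistic matches to
  two decimals; unstated conventions of the original run (e.g. whether
  sampling vectors were redrawn each iteration) are the likely cause,
  and both values are well within the published model-acceptance
  cutoffs.
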