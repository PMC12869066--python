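# Methods

This note documents the models, the estimation machinery, the
synthetic-data generator, and the numerical and design choices behind
them.

## Data model

The unit of analysis is a *record*: one phenotype for one inbred line in
one environment. Environments are discrete cells of a covariate grid
(here sex × temperature, coded female=0/male=1 and °C). Records are kept
in fixed line-major, environment-minor order so that incidence matrices
and record-level kernels are bit-reproducible across runs. Dosages count
alternate-allele copies; for fully inbred lines they are effectively
{0, 2}, but heterozygous calls are retained as 1 rather than purged.

Variant filters follow the usual panel conventions: minor-allele
frequency `min(f, 1−f) ≥ 0.05` and missing rate `≤ 0.2`, with equality
surviving both filters (removal is strict). Complete-case line filtering
drops every record of a line that lacks a phenotype in any required
environment, leaving a complete line × environment grid. By default
variants are filtered *after* line removal (frequencies computed on the
retained lines); a flag reverses the order.

## Kernels

- **G** (VanRaden): `WW' / (2Σ_k f_k(1−f_k))`, `W` the dosage matrix
  mean-filled at `2f` per variant and column-centered. Monomorphic
  variants are excluded from numerator and denominator alike. The entry
  sum of G is exactly zero (column centering), and the mean diagonal is
  ≈2 for inbred 0/2 dosages.
- **E**: `X̃X̃'/c` over records, where `X̃` column-standardizes the
  covariates (sex codes and °C are incommensurate; raw mode exists for
  sensitivity checks). The 1/c proportionality constant and the
  standardization flag are recorded in kernel metadata.
- **ZGZ'**: the incidence expansion of G to record level — a pure index
  lookup, so PSD is inherited.
- **ZGZ'∘E**: the Hadamard product, PSD by the Schur product theorem.

No kernel is trace-normalized: PVE is reported on the kernels as defined,
so the variance components are on the same scale the models state. This
means the *realized* variance contributed by a component is `σ²_k` times
the kernel's mean diagonal (≈2 for the genetic kernel), which matters
when comparing empirical component variances to `σ²` targets.

## REML engine

All four single-trait kernel models share one engine. The restricted
log-likelihood of `y = 1μ + Σ_k u_k + ε` is maximized over
`(σ²_1..σ²_m, σ²_ε)` by Newton steps on log-components using the
average-information matrix, with step-halving whenever a proposal fails
to improve the likelihood, and an EM-REML fallback step
(`σ² ← σ² + σ⁴(y'PKPy − tr(PK))/q`, monotone by construction) when no AI
step is acceptable. Components driven below `1e-10 × var(y)` are pinned
to exactly zero — this is what makes "genetics explains no variance"
representable as PVE 0 rather than a tiny positive number. Convergence is
a relative log-likelihood change below `1e-8` (default, max 200
iterations). A singular covariance gets a ridge jitter of `1e-8 × mean
diag` with a warning; a constant phenotype short-circuits to the
degenerate all-zero fit.

Each iteration costs one Cholesky factorization and one explicit inverse
of the q×q covariance; traces `tr(PK_k)` are then elementwise sums, so a
four-kernel fit at q≈1000 runs in a couple of seconds on one core.
Standard errors come from the inverse AI matrix at the optimum.
Predictions for held-out records use
`ŷ = μ̂ + Σ_k σ̂²_k K_k[test,train] V⁻¹(y−μ̂)`, which is equivalent to
solving Henderson's mixed-model equations on the joint system (asserted
in the tests to 1e-8).

## Multi-trait Gibbs sampler

`Y = 1m' + A + R` with `A ~ MN(0, G, Σ_A)` and diagonal `Σ_R`. After the
one-off eigendecomposition `G = UDU'`, the rotated rows of A are
independent, so the A-update is n independent r×r Gaussian draws; `Σ_A`
has an inverse-Wishart full conditional, each `Σ_R[j,j]` a scaled
inverse-χ², `m` a Gaussian (flat prior), and missing cells are sampled
from their predictive normal (data augmentation) — which is precisely
what makes held-out-cell prediction coherent. Chains are bit-reproducible
given a seed.

Priors default to weakly-informative conjugate forms: `Σ_A ~ IW(r+2,
0.5·diag(var_j))`, `Σ_R[j,j] ~ scaled-inv-χ²(5, 0.5·var_j)`; both are
configurable, and posterior sensitivity to them is a reportable quantity,
not an assumption. The production chain profile is 300,000 iterations,
200,000 burn-in, thinning 50; tests and desk-scale runs use a named
reduced profile (6,000 / 2,000 / 4). Genetic correlations are computed
per retained draw and then averaged (not from the mean covariance);
heritabilities likewise.

Two identifiability facts shaped the validation design:

1. With a single record per line and *unrelated* lines, `G ≈ 2I` and
   `σ²_A` vs `σ²_R` trade off along a nearly flat likelihood ridge. The
   posterior mean of a correlation `Σ_A[j,k]/√(Σ_A[j,j]Σ_A[k,k])` is then
   biased upward (Jensen's inequality over the ridge), regardless of how
   weak the priors are. Parameter-recovery checks therefore use the
   block-family genotype mode, whose within-family relatedness pins the
   genetic variance down.
2. A posterior mean and a REML mode agree only asymptotically; at finite
   n they differ by a systematic O(1/n) term that Monte-Carlo error does
   not bound (MC error can be made arbitrarily small by running the chain
   longer, the gap cannot). The estimator cross-check is therefore
   asserted at half a posterior SD — the Bernstein–von Mises scale on
   which the two shrink together — rather than at a multiple of the MC
   standard error.

Because the trait list is fixed by Y's columns, the model cannot predict
into an environment that was never observed; the API deliberately offers
no way to request it, and the CV driver reports the combination as
"not fittable".

## Random regression model

`y_ij = Σ_t(β_t + a_it)φ_t(j) + ε_ij` with plain (unnormalized) Legendre
polynomials on the gradient normalized to [−1, 1] from the *training*
environments; Kirkpatrick-style √((2t+1)/2) scaling is absorbed into
`Σ_a` and β and is deliberately not applied. The coefficient covariance
is (T+1)×(T+1) — intercept and slope at the default T=1 — and residual
variances are per-environment.

The phenotypic covariance is linear in the entries of `Σ_a` and the
residual variances: `V = G_rec ∘ (ΦΣ_aΦ') + diag(σ²_env)`. REML therefore
uses the same average-information Newton machinery, directly on these
linear components (the off-diagonal of `Σ_a` may be negative), with
step-halving to keep the likelihood non-decreasing and residuals
positive; `Σ_a` is eigenvalue-clipped to the PSD cone on exit if
numerical noise pushed it outside (flagged as a boundary fit). Line
coefficients for *all* lines in the GRM — including lines unseen in
training — are obtained by BLUP through genomic relationships, so unseen
unrelated lines fall back to the fixed trajectory.

The environmental gradient value is the per-environment mean phenotype of
the training records. A held-out environment consequently has no gradient
value; the fitter refuses to invent one, and a caller must supply it
explicitly. The CV driver treats an unsupplied value as "not fittable";
the analysis scripts pass the held-out environment's phenotype mean and
label it as an upper bound, since that quantity would not be observable
without leakage in a genuine new-environment setting. Predictions at
gradient positions outside the training range are allowed with an
extrapolation warning. At T=1 every line's prediction is exactly affine
in the normalized gradient, and the per-line R² of the linear reaction
norm is reportable as a diagnostic of whether a linear approximation
suffices.

## Cross-validation

Plans store explicit record-index partitions (JSON-serializable for exact
re-runs). Random Lines draws `round(0.17·n)` lines per replicate — 30 of
176 — and Random Observations `round(0.17·q)` records — 180 of 1,056;
replicates are independent redraws, not disjoint folds ("repeated",
not "partitioned"). New Environment is deterministic: one fold per
environment. Accuracy is the R² of the OLS regression of true on
predicted values, equal to the squared Pearson correlation and invariant
to affine transformations of the predictions. Constant predictions (e.g.
E-BLUP inside a single environment, or E-BLUP predicting into an unseen
environment) make that regression undefined; the value is reported as 0
with an explicit flag. Within-environment R² averages the per-environment
values unweighted (environments are equally sized on a complete grid).

## Synthetic-data generator

The generator emulates the study design end to end: n=176 unrelated fully
inbred lines (independent 0/2 dosages, allele frequencies uniform on
[0.05, 0.5], 5,000 variants, no linkage disequilibrium), a 2×3
sex-by-temperature grid (18/25/28 °C), all q=1,056 cells phenotyped, and
phenotypes drawn from the full interaction model with variance fractions
(0.12, 0.72, 0.08, 0.08) of a unit total variance around an intercept of
50 (lifespan-like in days; the scale is cosmetic, every check is
scale-free). Component draws use the same kernel constructions the
fitters use — generation and fitting form a closed loop, so REML recovers
exactly the σ² values the generator used — and each phenotype decomposes
*exactly* into its stored components.

What the generator does not emulate: linkage disequilibrium, selection,
the survival process underlying lifespan, residual heteroscedasticity,
and non-linear reaction norms. Passing tests therefore demonstrate
estimator correctness under the stated generative model, not robustness
to those real-data features. One consequence of the model worth knowing:
the environmental effect is a single rank-2 draw of six values, so its
realized variance varies enormously between seeds (a ±100% relative
spread is normal). Mean recovery over ≥20 seeds is the meaningful
statement; single-seed PVE splits can look far from (12, 72, 8, 8)
without anything being wrong. A block-family mode (sib-groups sharing a
founder genotype with probability 0.9, 22 families by default) exists to
probe how training–test relatedness changes the whole-line holdout
results and to provide well-identified designs for parameter-recovery
checks.

## Validation scales

The statistical acceptance tests run at the design scale where the claim
demands it (176 lines × 6 environments × 5,000 variants, 20 replicate
simulations for recovery and CV-structure checks; 1,500 variants where
only the GRM's rank matters; reduced Gibbs chains), and at toy scale
(12–26 records) where the oracle is exact — a likelihood grid, balanced
ANOVA closed forms, or a dense Henderson solve. The structural CV
expectations on the synthetic defaults are: environment-only prediction
is null in held-out environments; genetics-only prediction is null for
held-out unrelated lines; modelling the interaction improves held-out-cell
prediction and does not improve held-out-line prediction beyond Monte-Carlo
noise.

## Known limitations

- Fixed effects are intercept-only (per-basis-order for the RRM); no
  general covariate design.
- `Σ_R` of the multi-trait model is diagonal by construction.
- Gibbs diagnostics are limited to autocorrelation-based effective sample
  sizes; no multi-chain statistics.
- The RRM optimizer treats a non-improving iteration as converged; on
  pathological likelihoods this reports a boundary/flagged fit rather
  than searching globally.
- CV replicates are independent redraws, so their mean is not an unbiased
  k-fold estimate; it matches the repetition design it implements.
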