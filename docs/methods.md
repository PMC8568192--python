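# Methods

## Model

`dnmjoint` models per-gene de novo mutation (DNM) counts from trio
sequencing studies of one or two early-onset traits. For gene *i* with
mutability *μᵢ* (probability of a damaging-class DNM per haploid genome per
generation) and a case cohort of *N* trios, the null expected count is
2*N·μᵢ*. Counts are Poisson:

- single trait: a latent Bernoulli(π) indicator *Zᵢ* marks risk genes;
  *Yᵢ | Zᵢ=0* ~ Poisson(2*Nμᵢ*), *Yᵢ | Zᵢ=1* ~ Poisson(2*Nμᵢγᵢ*);
- two traits: a four-way latent class *Zᵢ* ∈ {00, 10, 01, 11} with prior
  π = (π₀₀, π₁₀, π₀₁, π₁₁) marks which traits the gene is associated with;
  each trait's count is Poisson with the null mean, inflated by the trait's
  relative risk *γᵢₜ* in classes carrying that trait's risk. Counts are
  conditionally independent across traits given the class.

The excess of π₁₁ over the independence product (π₁₀+π₁₁)(π₀₁+π₁₁) measures
global pleiotropy between the traits. Functional annotations enter through
an exponential link on the relative risk, γᵢₜ = exp(xᵢₜ'βₜ), with an
intercept-only design recovering a shared relative risk exp(β₀) per trait.
The model assumes risk genes are enriched (γ > 1); we do not enforce this as
a constraint during estimation — a warning is logged if a fitted intercept
is non-positive.

## Estimation

Parameters Θ = (π, β₁, β₂) are estimated by EM:

- **E-step**: class posteriors by Bayes' rule, computed in log space
  (Poisson log-pmfs assembled from `gammaln`, mixed by log-sum-exp), so no
  pmf underflows even for large count/mean discrepancies.
- **M-step**: π is the column mean of the posterior (analytic). For each
  trait's β, the expected complete-data log-likelihood *Q* is concave; with
  an intercept-only design the maximizer is analytic,
  β = log(Σwᵢyᵢ / Σwᵢ·2Nμᵢ) with wᵢ the posterior risk weight; with
  annotations we run safeguarded Newton–Raphson (analytic gradient and
  Hessian, step halving whenever *Q* would decrease, ridge regularization of
  a numerically singular Hessian), warm-started from the previous iterate.

Defaults (all exposed via `FitOptions`): EM stops when the relative change
of the observed-data log-likelihood falls below 1e-8 or after 5,000
iterations; Newton stops at gradient ∞-norm 1e-8 or 100 steps; ridge 1e-8.
Initialization is deterministic: π⁰ = (0.90, 0.04, 0.04, 0.02) (single
trait: (0.9, 0.1)); the β intercept starts at log max(1.5, ΣY/Σ2Nμ) — a
moment estimate floored so the initial relative risk exceeds 1, matching
the model's assumption — and other coefficients at 0. Class proportions
whose posterior mass collapses below 1e-12 are floored and renormalized so
EM stays defined on degenerate data. The observed-data log-likelihood is
non-decreasing across iterations; the test suite asserts this on every fit.

**Identifiability at the null.** When the data contain no real signal the
mixture is unidentifiable in the γ → 1 limit: EM can leave prior mass in
"risk" classes whose fitted relative risk is near 1. Such fits are
statistically equivalent to the null — the implied excess burden is
negligible and no gene is rejected — but π̂₀₀ itself need not approach 1.

## Annotation collapsing and feature selection

Variant-level annotation scores of the observed DNMs are summed within each
gene; a first-order expansion of the per-gene likelihood ratio shows this
sum is the sufficient gene-level feature when per-variant effects are small,
provided continuous scores are centered at their DNM-wide mean first.
Defaults: centering on for continuous scores, off for binary flags (which
collapse to plain counts, e.g. the LoF burden); missing variant values are
mean-imputed with a logged tally; genes without DNMs score 0. Gene-level
features are standardized to mean 0, standard deviation 1 using the
population (1/n) deviation — an arbitrary but fixed convention; constant
columns are dropped.

Feature selection is two-stage, run separately per trait on its single-trait
model: (1) greedy Pearson-correlation pruning in input column order —
a later feature is dropped when its signed correlation with any kept
feature exceeds 0.7 (an `absolute` switch compares |r| instead; the signed
rule is the default, taken literally from the selection rule's statement);
(2) fit, keep features with fitted |β| > 0.01, and refit on the survivors.
Both stages are pure functions of their inputs; reports are byte-identical
across runs.

## Testing

For trait 1 the joint local false discovery rate of gene *i* is the
posterior probability of the trait-1 null, Jlfdr₁ = Pr(Z₀₀+Z₀₁ = 1 | Y₁,Y₂)
— the sum of the (00) and (01) posterior columns; symmetrically for trait
2. Sorting Jlfdr ascending, the false discovery rate of rejecting the *a*
smallest values is their running mean; the threshold is the largest value
whose running mean stays at or below the nominal level *q* (default 0.05),
and every gene at or below it is rejected. Because the rejection region is
{Jlfdr ≤ t}, ties are rejected as whole blocks and candidate cuts are
evaluated only at tie-block boundaries; this keeps the mean Jlfdr of the
rejected set at or below *q* in all cases, and coincides with the plain
order-statistic rule whenever the values are distinct. The Jlfdr is a
plug-in quantity computed at the EM estimate Θ̂; no uncertainty in Θ̂ is
propagated. Single-trait testing applies the identical machinery to the
two-class posterior.

## Simulation engine

The generator reproduces the operating conditions of the method's
evaluation study and is first-class, tested code:

- **Mutabilities**: log₁₀ μ ~ Normal(−5, 0.7) truncated to [−8, −3.5]. The
  evaluation design samples real exome genes; we substitute this law
  (configurable, or a user-supplied table) to remove the data dependency
  while matching the scale and spread of damaging-class mutabilities
  (median 1e-5, range ~1e-8 to 3e-4).
- **True model**: M = 10,000 genes; latent classes multinomial(π) with
  marginal risk proportions 0.1 per trait and shared proportion π₁₁ varied
  in 0.01–0.09; per-trait i.i.d. Bernoulli(0.5) annotations; relative risk
  exp(x'β) with intercept 3 and effects 0.1/0.3/0.5 (weak/moderate/strong);
  cohort sizes 2,000 / 5,000 / 10,000. In power settings three annotations
  act but only the first two are observed by the analyst (configurable
  mask), emulating partially observed functional information.
- **Misspecified model**: annotations act on the latent class through a
  multinomial-logistic link — implemented via the equivalent factorization
  into two independent per-trait logistic Bernoulli draws — with logistic
  intercept −3 and effects 0.5/1/1.5, a fixed relative risk of 25, and
  cohorts of 1,000 / 2,000 / 4,000.
- **Scoring**: 50 replicates per setting, seeded `base_seed + replicate` so
  grids are deterministic and all methods see identical data within a
  replicate. Power = rejected risk genes / risk genes; empirical FDR =
  false rejections / max(1, rejections); type-I = false rejections / null
  genes; AUC ranks true risk status by 1 − Jlfdr (ties counted ½).
  Summaries report means ± Monte-Carlo standard errors.

What the generator does *not* emulate: real mutability heterogeneity tied
to gene length and sequence context, correlated or continuous annotations,
overlapping samples between cohorts, and cross-study filtering differences.
Passing tests therefore demonstrate correctness of the estimator and the
FDR machinery under the stated generative conditions, not performance on
any particular real cohort.

## Numerical and design choices

- Class order is fixed as (00, 10, 01, 11) everywhere, including on-disk
  posterior columns.
- All mixture arithmetic is in log space; a naive probability-space
  evaluation agrees to 1e-10 on small means and is used as a test oracle.
- Counts are never capped; the Poisson log-pmf is evaluated exactly.
- Genes with non-positive or missing mutability are rejected at load time
  with the offending identifiers named.
- Jlfdr column sums are clipped to [0, 1] (they can exceed 1 by one ulp
  after exp-normalization).
- Fits are deterministic given inputs: no randomized initialization.

## Problem sizes

The replicate studies in the test suite and the acceptance script use the
full evaluation-scale conditions — 10,000 genes, 50 replicates, cohort
sizes 2,000–10,000 — since a single fit takes well under a second. The
feature-selection simulation uses one replicate at the same gene count.

## Limitations

Two traits only (the latent class count grows as 2^K in the number of
traits); no standard errors or credible intervals for Θ̂; no p-values (the
partial ordering of two-dimensional count vectors needed to define one is
out of scope); mutabilities are consumed as input, never estimated;
transmitted variants are not modeled.
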