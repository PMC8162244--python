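# Methods

## Model and decomposition

`varpart` works on random-intercept (generalized) linear mixed models

    y = Xβ + Σₖ Zₖαₖ + ε (Gaussian),    g(E[y|α]) = Xβ + Σₖ Zₖαₖ (GLMM)

with any number of crossed random intercepts αₖ ~ N(0, σ²_αₖ). All R²-type
statistics live on the link (latent) scale and are ratios of four variance
components:

| component | meaning | source |
|---|---|---|
| Y_X | var(Xβ̂) across observations | linear predictor of the fitted model |
| Y_RE | Σₖ σ̂²_αₖ (OLRE excluded) | estimated intercept variances |
| Y_R | σ̂²_ε (Gaussian) or OLRE variance (non-Gaussian) | residual / overdispersion |
| Y_D | distribution-specific variance | family + link (see below) |

Total (marginal) R² is Y_X / (Y_X + Y_RE + Y_D + Y_R). The component sum
is a population-level quantity given the model; it is close to, but not
exactly, the sample variance of the raw response (checked within ~10% on
well-specified Gaussian simulations).

Part (semi-partial) R² of a term set is (Y_X − Y_X̃)/Y_Total: the reduced
model is refitted from scratch — same random structure, family and link,
all variance parameters re-estimated — and only the numerator changes; the
denominator is always the full model's Y_Total so that values are
comparable across sets and additive under orthogonality. Partial R²
(which rescales by the reduced model's unexplained variance and is always
larger) is deliberately not computed; it can be derived from the reported
Y_X̃ if needed.

Structure coefficients are Pearson correlations cor(η, xⱼ) per
non-intercept design column; inclusive R² = SC²·R²; beta weights are
β̂ⱼ·sd(xⱼ)/sd(y) for Gaussian models and β̂ⱼ·sd(xⱼ)/√Y_Total for
non-Gaussian ones (the observed-scale sd would mix data and link scales;
the choice is recorded in the output metadata). All three are reported per
model-matrix column, not per term: correlations are defined for columns,
and no canonical term-level aggregate exists for multilevel factors.

## Distribution-specific variance

Gaussian: 0. Binomial: π²/3 (logit), 1 (probit). Poisson: 1/4 (sqrt
link); for the log link, ln(1 + 1/λ) where λ is the marginal count mean.
By default λ is reconstructed on the latent scale via the lognormal mean,
λ = exp(β̂₀c + (Y_RE + Y_R)/2), where β̂₀c — the intercept the model would
have with all covariates mean-centered — is computed as the mean of the
linear predictor. `lambda_method="observed_mean"` substitutes the sample
mean of the counts; both choices are recorded in the metadata.

Poisson models and binomial models with >1 trial per row get an
observation-level random effect (a grouping column with one level per row)
added automatically unless one is already present; its variance is the
overdispersion component Y_R. Binary responses cannot express
overdispersion this way and are left untouched.

## Estimation

Gaussian REML: the covariance is written V = σ²_ε(I + ZΛΛ'Z') with Λ
block-diagonal in the sd ratios sₖ = σ_αₖ/σ_ε. β and σ²_ε are profiled
out; the objective is evaluated from the sufficient statistics
(Z'Z, Z'X, Z'y, X'X, X'y, y'y), so one evaluation is O(q³) in the total
number of random levels q, never O(n³). The outer optimizer is bounded
L-BFGS-B on s ∈ [0, 50] with finite-difference gradients; the lower bound
sits exactly at zero so boundary fits are representable. On balanced
one-way designs the estimates equal the classical ANOVA estimators
(σ̂²_α = (MSB − MSW)/m, σ̂²_ε = MSW), which the tests verify, along with
agreement with statsmodels MixedLM on single-group designs.

Poisson/binomial Laplace ML: writing b = Λu with u ~ N(0, I), the joint
mode of (β, u) at fixed Λ is found by penalized IRLS on the working
response (tolerance 1e-8 on the linear predictor, with step-halving on the
penalized deviance). The Laplace objective

    −2ℓ = −2 log f(y | μ̂) + û'û + log det(ΛZ'WZΛ + I)

is minimized over the latent-scale sds s ∈ [0, 10] by L-BFGS-B (outer
tolerance 1e-6), warm-starting the inner loop between evaluations.
Binomial proportion data enter as (successes, failures) pairs: the
response is the proportion and the trial count is a prior weight. Linear
predictors are clipped at ±30 (logit/log) to keep weights finite under
near-separation; IRLS weights are clipped to [1e-12, 1e12] and singular
trial systems during outer exploration return a large penalty instead of
aborting the fit. At the s = 0 boundary the fit coincides with an ordinary
GLM (verified against statsmodels to 1e-4).

Variance estimates with sd below 1e-5 are reported as exactly 0 with a
recorded boundary warning — bootstrap resamples hit this boundary often
and it must not be fatal. Non-convergence likewise produces a flagged
result, not an exception.

## Formula dialect and reduced designs

Formulas use Wilkinson notation with `+`, `*`, `:` and `(1|group)` random
intercepts. Random slopes, `a/b` nesting and in-formula transformations
are rejected — transformed columns must be precomputed, because partition
terms are matched *string-exactly* against model terms (interaction labels
are canonicalized to data-column order, so `b:a` ≡ `a:b`). Missing values
are an error, not silently dropped.

Fixed-effect designs are built by patsy with treatment contrasts (first
level in sorted order as reference). Reduced designs re-expand the
surviving terms from scratch, which reproduces the marginality behaviour
of the R mixed-model ecosystem: removing a main effect that participates
in an interaction regenerates the interaction block with a full dummy set,
so ndf may not drop (e.g. 6 → 6 when removing a continuous main effect
crossed with a 3-level factor, vs 6 → 4 when removing the interaction).
A consequence worth knowing: in that situation the reduced design spans
the same column space as the full one, so the naive part R² of such a main
effect is structurally ~0. `dummy_center` exists for exactly this case —
with mean-centered dummy columns the main effect estimates the average
effect across levels and can be partitioned meaningfully; `merge_runs`
supports the alternative of estimating main effects from the model without
their interaction and merging the two runs into one table.

Reduced fits are cached by the surviving term set (different drop sets can
reparametrize to identical designs). The drop set containing *all* fixed
terms reuses the full fit: its reduced linear predictor is constant, so
Y_X̃ = 0 and part R² equals total R² exactly rather than up to refit noise.

## Bootstrap

Parametric: each iteration draws fresh random intercepts (and OLRE values)
from the estimated variances, adds them to Xβ̂, samples the response from
the fitted family, refits the full model and recomputes every statistic.
Intervals are percentile intervals with the median-unbiased quantile
definition (the simplest defensible default; labelled in the metadata).
Negative part-R² draws — which arise legitimately when removing a weak
predictor shifts variance into the random effects — are clamped to zero
*before* quantile computation by default; `allow_neg_r2=True` retains
them. Failed refits are dropped and counted, never imputed, and the point
estimate is never forced inside the interval: an estimate outside its own
bootstrap CI is a diagnostic worth surfacing. Iteration i uses the random
substream `default_rng([seed, i])`, so results are bit-identical for a
given master seed regardless of how many workers run the iterations
(`max_workers` uses joblib processes).

## Synthetic data and what the tests show

`SimScenario`/`simulate_dataset` generate datasets with standardized
multivariate-normal predictors, optional balanced factor, group intercepts
and family sampling, plus a closed-form truth record: under x ~ N(0, Σ)
with effects β, Y_X = β'Σβ, the reduced model's large-sample Y_X̃ is the
projection c'Σ_SS⁻¹c (c = (Σβ)_S for retained set S), structure
coefficients are (Σβ)ⱼ/√Y_X, and part R²/inclusive R² follow. These
linear-algebra identities are the brute-force oracle the refit-based
estimator is tested against. Default scenario: 25 groups × 20
observations, β = (0, 1, 0.5) on independent unit-variance predictors,
group and residual variances 0.5 — the configuration whose total R² is
1.25/2.25 ≈ 0.556. `guinea_pig_like` emulates a repeated-measures hormone
study: 31 subjects × 3 time points, a time factor crossed with a
continuous standardized rank index, subject random intercepts, and a
configurable rank-by-time interaction.

The generator draws group intercepts i.i.d. normal, predictors without
group structure, and balanced group sizes. Real data violate all three
(unbalanced designs, predictors varying mostly between or within groups,
non-normal intercepts), so passing recovery tests demonstrates
correctness of the estimators under the stated model, not robustness to
misspecification. Problem sizes in the test suite (n up to 5000 for
recovery, 200 replicates × 200 bootstrap iterations for CI coverage,
averaging over 4 replicate datasets per scenario in the oracle-agreement
suite) were chosen so each check's Monte-Carlo error is small relative to
its tolerance.

## Known limitations

- Random intercepts only — no random slopes, no autocorrelated residuals.
- No quasi-likelihood or negative-binomial family; overdispersion is
  handled exclusively through the OLRE.
- Conditional R² (fixed + random) and full commonality decompositions are
  not reported; both are derivable from the exported components.
- The Laplace approximation is known to bias variance estimates for
  binary data with few observations per group; nothing here corrects that.
- Term-level aggregation of structure coefficients for multilevel factors
  is intentionally absent (no canonical definition).
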