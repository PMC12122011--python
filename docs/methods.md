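# Methods

## Model and estimand

W outcomes Y₁…Y_W are each regressed on the same fixed design matrix
X ∈ ℝ^{N×C} (intercept, one exposure of interest, optional adjusted
covariates), with homoscedastic errors and df = N − C. The quantity of
interest is θ̂, the number of outcomes whose exposure coefficient is
rejected at an *uncorrected* per-test level α, compared against the
distribution θ̂⁰ it would have if **all** W null hypotheses held (the global
null). Rejection is strict (p < α): ties at exactly α are non-rejections, a
measure-zero event for continuous statistics. Tests are two-sided by
default; one-sided alternatives are available via `fit_ols_many(...,
alternative=)` since nothing in the counting logic depends on direction.

## Resampling under the global null

`run_resampling` implements residual-row resampling with the design fixed:
resampled outcomes are fitted values plus whole residual rows drawn with
replacement (shared indices across outcomes, preserving both the
outcome–covariate correlations and the residual correlations between
outcomes), and resample statistics are centered at the original estimates.
Validity rests on the distribution of β̂_w − β_w = (X′X)⁻¹X′ε_w depending
only on the error distribution, not on β_w, so the scheme recovers the
global-null law of the test statistics even when the data were generated
under alternatives. Three intuitive alternatives (resampling outcome
vectors, parametric bootstrap with the null imposed, whole-row case
resampling) do *not* have this property and are deliberately not
implemented.

Numerical/implementation choices:

* **Vectorized refitting.** With X fixed, β⁽ʲ⁾ − β̂ is the exposure row of
  (X′X)⁻¹X′ applied to the drawn residual rows R, and the resample RSS is
  ‖R‖² − ‖Q′R‖² with Q an orthonormal basis of col(X). This is an exact
  algebraic identity with per-resample refitting (asserted in tests) and
  reduces each resample to a few small matrix products; resamples are
  processed in chunks of 128 to bound memory.
* **Residual sign.** We resample ε̂ = Y − Ŷ (the standard convention); a
  printed variant of the algorithm uses the negated residual. For the
  exchangeable row-resampling scheme the two differ only in the sign of
  T⁽ʲ⁾, so two-sided inference is bit-identical; `negate_residuals=True`
  reproduces the other convention exactly.
* **Variants.** `variant="residual-only"` uses the resampled residual rows
  alone as outcomes with uncentered statistics (the Westfall–Young OLS
  scheme). For OLS both variants yield identical |T⁽ʲ⁾| given the same
  index draws — (I−H)(Ŷ+R) = (I−H)R and the centered numerator equals the
  uncentered one — which the test suite asserts exactly rather than merely
  within Monte-Carlo error. Both are exposed because they generalize
  differently beyond OLS.
* **Degenerate resamples.** σ̂⁽ʲ⁾ = 0 (possible only for tiny/degenerate
  inputs) sets the statistic to 0 with a warning — conservative, since it
  cannot inflate the resampled count.
* **Reference distribution.** Resample p-values use t(N − C), matching the
  original tests; `reference="normal"` is available for large N.
* **RNG contract.** One seeded `numpy` Generator; the B×N index draws are
  consumed in j-major order, so runs are reproducible across platforms and
  chunk sizes.

## Metrics

* **Null interval**: inverse-CDF (order-statistic) quantiles of the B
  counts at (1−level)/2 and 1−(1−level)/2. Integer limits by construction,
  matching the exact Binomial(W, α) interval in the independence limit;
  interpolating quantile conventions would produce non-integers for a count
  statistic.
* **Excess hits**: θ̂ − θ_hi, negative allowed. Under subset pivotality
  (which holds for these OLS statistics), θ_hi bounds the number of false
  positives among the observed rejections in ≥95% of repeated samples, so
  max(0, excess hits) acts as a familywise rejection count.
* **Global test**: p = #{j : θ̂⁽ʲ⁾ ≥ θ̂}/B, the plain empirical tail
  proportion (weak inequality; can be exactly 0). The (#{≥}+1)/(B+1)
  correction is available but off by default. The per-test α and the
  familywise α_W are independent knobs: a 99% interval gives 0.01-level
  familywise statements regardless of the α at which counts were taken.
* **Binomial reference**: exact Binomial(W, α) expected count, interval and
  tail p under independence — anticonservative when outcomes are positively
  correlated, included to quantify exactly how misleading independence
  intuition is.

## FWER comparators

Bonferroni and Holm are delegated to statsmodels' `multipletests`
(closed-form, assumption-free). minP and Wstep adjust observed p-values by
the distribution of resample p-value minima (single-step and step-down with
monotonization); Romano–Wolf is implemented in its max-|T| step-down form on
the centered resample statistics, with inverse-CDF critical values and
strict exceedance for rejection, re-estimating the critical value after each
rejection round. Each method doubles as a global test (reject iff ≥1
familywise rejection at α_W). FDR procedures, Šidák-type independence
corrections and k-FWER are out of scope.

## Synthetic data

`generate_dataset` draws N i.i.d. rows from a multivariate standard normal
over (X, Y₁…Y_W) with unit variances: pairwise outcome correlation ρ_YY,
exposure–outcome correlation ρ_XY for the first q·W outcomes and 0 for the
rest. This emulates the canonical outcome-wide setting — equicorrelated
continuous outcomes, a single continuous exposure, linear effects,
homoscedastic normal errors. It does **not** emulate skewed or discrete
outcomes, heteroscedasticity, unequal pairwise correlations, missing data,
or confounding beyond what covariate adjustment represents; passing tests
therefore certify the resampling machinery and its calibration under this
clean model, not robustness to those violations. Parameter combinations
whose implied correlation matrix is not positive semidefinite (smallest
eigenvalue < −1e−8) are rejected, and grid runs prune them into a manifest.

## Simulation scale

Scenario defaults are nsim = 100 replicates with B = 500 resamples (the
library itself is routinely run at 500/1000, available by config); the
bundled reproduction script uses nsim = 300 datasets with B = 1000 for the
null-interval means and 4000 fit-only datasets for the mean observed
rejection count, reporting Monte-Carlo standard errors alongside every mean
so that comparisons are made within stated uncertainty. A master
`SeedSequence` spawns one child per replicate, making scenarios reproducible
and order-independent. The mean observed-rejection scenario fixes
ρ_YY = 0.60; the mean of θ̂ is invariant to ρ_YY (marginal per-test power
does not depend on it, a tested property), so this choice affects only the
Monte-Carlo variance of that mean.

## Known limitations

* Only identity-link OLS models: valid global-null resampling for GLMs with
  non-identity links is an open problem, and robust/sandwich or weighted
  variants are not offered because the resampling theory is stated for
  homoscedastic OLS.
* Missing data are refused rather than dropped: silent complete-case
  filtering would change the fixed design mid-analysis.
* The global test dichotomizes p-values at α, losing information when
  evidence concentrates in a few very small p-values; the FWER comparators
  (especially Romano–Wolf) can be more powerful there, which the simulation
  harness makes easy to see.
* The closed-form variance of the null count given pairwise p-value
  correlations is not implemented.
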