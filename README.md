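# excesshits

Global evidence-strength metrics for multiple testing with **correlated**
outcomes.

## The problem

Outcome-wide epidemiologic studies (and multiverse/specification-curve
analyses) test one exposure against many outcomes fitted on the same design
matrix, so the W test statistics are correlated. Classical answers —
Bonferroni/Holm, Westfall–Young minP/Wstep, Romano–Wolf — penalize each
individual p-value to control the familywise error rate, but none of them
directly answers: *how many uncorrected rejections would chance alone
produce here, given the correlation structure?* Ten rejections out of 40 at
α = 0.05 is striking if the tests are independent (expect W·α = 2) and
possibly unremarkable if they are strongly correlated.

## The method

Let θ̂ = #{w : p_w < α} be the observed number of α-level rejections across
the W shared-design OLS models Y_w = γ₁ + β_w X + Σ γ_j X_j + ε_w. The
package estimates the sampling distribution of θ̂ under the **global null**
(all β_w = 0) by residual-row resampling with the design held fixed:

1. fit all W regressions once; keep fitted values Ŷ and residual rows ε̂;
2. for each resample j, draw row indices n′(1..N) with replacement, shared
   across outcomes, and set Y⁽ʲ⁾ = Ŷ + ε̂_{n′} (covariates untouched);
3. refit and form centered statistics
   T⁽ʲ⁾_w = (β̂⁽ʲ⁾_w − β̂_w) / (σ̂⁽ʲ⁾_w √[(X′X)⁻¹]_ee),
   which behave as if every null held even when the data carry real effects;
4. convert to p-values on t(N−C) and count rejections θ̂⁽ʲ⁾ per resample.

From the B counts it reports a **95% null interval** (inverse-CDF
2.5th/97.5th percentiles), the **excess hits** θ̂ − θ_hi, a familywise
rejection count max(0, excess hits), and a one-sided **global test** with
p = #{j : θ̂⁽ʲ⁾ ≥ θ̂}/B — plus the exact Binomial(W, α) independence
reference and the five FWER comparators run from the same resamples.

## Worked example

```bash
python examples/global_metrics_basic.py
```

generates 800 subjects with 25 outcomes (pairwise correlation 0.30), half of
them truly associated with the exposure at r = 0.10, and prints:

```
Observed rejections at alpha=0.05: theta-hat = 11
95% null interval (B=1000 resamples): [0, 5]
Excess hits beyond the null interval: 6
Familywise rejection count at alpha_W=0.05: 6
Global test p-value: 0.001
```

Eleven of 25 raw tests reject; under the global null, correlation plus
chance would produce at most 5 rejections in 95% of samples, so 6 rejections
are in excess and the global null is rejected at p ≈ 0.001. See also
`examples/fwer_comparison.py` (all five FWER procedures on the same draws),
`examples/correlation_widens_null_interval.py` (why binomial intuition
fails), and `examples/simulation_scenario.py` (one Monte-Carlo power cell).

A thin CLI wraps the same functions for CSV datasets:

```bash
excesshits analyze --data cohort.csv --config analysis.yaml --out report/
excesshits simulate --grid grid.yaml --out sims/
```

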