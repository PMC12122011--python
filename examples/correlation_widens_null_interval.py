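"""How outcome correlation widens the null interval past the binomial one.

With W independent tests at alpha the null count is Binomial(W, alpha); with
correlated outcomes the same expected count spreads over a much wider range,
so binomial intuition ("10 of 40 must mean something!") overstates evidence.
"""

import numpy as np

from excesshits import (
    SimScenario,
    binomial_reference,
    generate_dataset,
    null_interval,
    run_resampling,
)

W, alpha = 40, 0.05
expected, binom_int, _ = binomial_reference(W, alpha)
print(f"independent reference: expect {expected:.2f} rejections, "
      f"95% interval {list(binom_int)}")

for rho_YY in (0.0, 0.30, 0.60):
    scenario = SimScenario(W=W, N=1000, rho_YY=rho_YY, q=0.0)
    data = generate_dataset(scenario, np.random.default_rng(3))
    draws = run_resampling(data, alpha=alpha, B=2000, seed=3)
    lo, hi = null_interval(draws, level=0.95)
    print(f"rho_YY={rho_YY:.2f}: resampled 95% null interval [{lo}, {hi}], "
          f"mean null count {draws.counts.mean():.2f}")

print()
print("Reading: the mean null count stays near W*alpha = 2 regardless of "
      "correlation, but the upper limit roughly triples between independent "
      "and strongly correlated outcomes — the same observed count can be "
      "strong evidence in one case and pure chance in the other.")
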