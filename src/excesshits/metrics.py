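"""Global evidence-strength metrics built on the resampled rejection counts.

Given the observed number of alpha-level rejections theta-hat and the B
resampled counts theta-hat(j) generated under the global null, report:

* a 1 - alpha_W "null interval" — the inverse-CDF 2.5th/97.5th percentile
  range of counts plausible if every null held,
* the "excess hits" theta-hat - theta_hi (may be negative),
* the familywise rejection count max(0, excess hits),
* a one-sided global test with p = #{j : theta-hat(j) >= theta-hat} / B,
* and, as an anticonservative independence reference, the exact
  Binomial(W, alpha) versions of the same quantities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GlobalMetrics",
    "null_interval",
    "excess_hits",
    "familywise_rejection_count",
    "global_test_pvalue",
    "binomial_reference",
    "compute_global_metrics",
]


def _counts(draws) -> np.ndarray:
    return np.asarray(draws.counts if hasattr(draws, "counts") else draws)


def _inv_cdf_quantile(sorted_vals: np.ndarray, q: float) -> int:
    """Smallest value whose empirical CDF reaches q (order-statistic convention)."""
    B = sorted_vals.size
    k = max(int(np.ceil(q * B)), 1) - 1
    return int(sorted_vals[k])


def null_interval(draws, level: float = 0.95) -> tuple[int, int]:
    """Integer (theta_lo, theta_hi) from the resampled counts.

    theta_lo / theta_hi are the smallest integers whose empirical CDF reaches
    (1-level)/2 and 1-(1-level)/2. Inverse-CDF quantiles keep the limits on
    the integer support of the counts, matching the exact-binomial
    construction in the independence limit.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    counts = np.sort(_counts(draws))
    tail = (1.0 - level) / 2.0
    return _inv_cdf_quantile(counts, tail), _inv_cdf_quantile(counts, 1.0 - tail)


def excess_hits(theta_hat: int, interval: tuple[int, int]) -> int:
    """theta-hat minus the null interval's upper limit; negative allowed."""
    return int(theta_hat) - int(interval[1])


def familywise_rejection_count(excess: int) -> int:
    """Rejected-null count at familywise alpha_W: max(0, excess hits)."""
    return max(0, int(excess))


def global_test_pvalue(theta_hat: int, draws, add_one: bool = False) -> float:
    """One-sided global-test p-value: share of resamples with >= theta-hat rejections.

    The plain empirical tail proportion (weak inequality) is the default and
    can be exactly 0; ``add_one`` applies the (#{>=} + 1)/(B + 1) finite-B
    correction instead.
    """
    counts = _counts(draws)
    hits = int(np.count_nonzero(counts >= theta_hat))
    if add_one:
        return (hits + 1) / (counts.size + 1)
    return hits / counts.size


def binomial_reference(
    W: int, alpha: float, theta_hat: int | None = None, level: float = 0.95
) -> tuple[float, tuple[int, int], float]:
    """Exact independence reference: what the metrics would be if the W
    tests were independent, from the Binomial(W, alpha) null distribution.

    Returns (expected count W*alpha, inverse-CDF null interval, exact tail
    p-value P(Bin(W, alpha) >= theta_hat)). Anticonservative under positive
    correlation: the true null interval is wider than this one.
    """
    if W < 0:
        raise ValueError("W must be nonnegative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    expected = W * alpha
    if W == 0:
        return expected, (0, 0), 1.0 if (theta_hat or 0) <= 0 else 0.0
    dist = stats.binom(W, alpha)
    tail = (1.0 - level) / 2.0
    lo = int(dist.ppf(tail))
    hi = int(dist.ppf(1.0 - tail))
    p = float(dist.sf(theta_hat - 1)) if theta_hat is not None else np.nan
    return expected, (lo, hi), p


@dataclass
class GlobalMetrics:
    """Reportable summary of global evidence strength."""

    theta_hat: int
    interval: tuple[int, int]
    excess_hits: int
    fw_rejections: int
    global_p: float
    alpha: float
    alpha_W: float
    B: int
    seed: int | None = None

    def to_json(self, **dump_kwargs) -> str:
        d = asdict(self)
        d["interval"] = list(self.interval)
        return json.dumps(d, **dump_kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GlobalMetrics":
        d = json.loads(text)
        d["interval"] = tuple(d["interval"])
        return cls(**d)

    def summary(self) -> str:
        lo, hi = self.interval
        lines = [
            f"Observed rejections at alpha={self.alpha:g}: theta-hat = {self.theta_hat}",
            f"{100 * (1 - self.alpha_W):g}% null interval (B={self.B} resamples): [{lo}, {hi}]",
            f"Excess hits beyond the null interval: {self.excess_hits}",
            f"Familywise rejection count at alpha_W={self.alpha_W:g}: {self.fw_rejections}",
            f"Global test p-value: {self.global_p:g}",
        ]
        return "\n".join(lines)


def compute_global_metrics(
    theta_hat: int,
    draws,
    alpha_W: float = 0.05,
    level: float | None = None,
    add_one: bool = False,
) -> GlobalMetrics:
    """Assemble all metrics from the observed count and the resampled draws.

    The interval level defaults to 1 - alpha_W but may be set independently
    (a 99% interval bounds false positives at the 0.01 familywise level no
    matter what per-test alpha produced the counts).
    """
    if level is None:
        level = 1.0 - alpha_W
    interval = null_interval(draws, level=level)
    excess = excess_hits(theta_hat, interval)
    return GlobalMetrics(
        theta_hat=int(theta_hat),
        interval=interval,
        excess_hits=excess,
        fw_rejections=familywise_rejection_count(excess),
        global_p=global_test_pvalue(theta_hat, draws, add_one=add_one),
        alpha=float(getattr(draws, "alpha", np.nan)),
        alpha_W=alpha_W,
        B=int(getattr(draws, "B", _counts(draws).size)),
        seed=getattr(draws, "seed", None),
    )
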