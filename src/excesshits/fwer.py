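"""Comparator FWER-control procedures and their use as global tests.

Five procedures that strongly control familywise error under arbitrary
correlation: the closed-form Bonferroni and Holm corrections, the
Westfall-Young single-step minP and step-down Wstep resampling adjustments,
and the Romano-Wolf step-down max-statistic procedure on centered resampled
statistics. Each doubles as a global test: rejecting at least one hypothesis
with familywise inference at alpha_W rejects the global null at alpha_W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjustedPvalues",
    "RomanoResult",
    "bonferroni",
    "holm",
    "minp_adjust",
    "wstep_adjust",
    "romano_stepdown",
    "global_test_from_fwer",
    "n_familywise_rejections",
]


@dataclass
class AdjustedPvalues:
    method: str
    raw: np.ndarray
    adjusted: np.ndarray

    def rejections(self, alpha_W: float = 0.05) -> np.ndarray:
        return self.adjusted <= alpha_W


@dataclass
class RomanoResult:
    """Step-down max-|T| result: rejection flags plus per-step critical values."""

    rejected: np.ndarray                   # (W,) bool
    critical_values: list[float]
    steps: list[list[int]] = field(default_factory=list)  # indices rejected per step
    alpha_W: float = 0.05


def _as_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(p) -> AdjustedPvalues:
    """One-step Bonferroni: adjusted = min(1, W * p)."""
    p = _as_p(p)
    adj = multipletests(p, method="bonferroni")[1]
    return AdjustedPvalues("bonferroni", p, adj)


def holm(p) -> AdjustedPvalues:
    """Holm step-down: running max of (W - k + 1) * p_(k), capped at 1."""
    p = _as_p(p)
    adj = multipletests(p, method="holm")[1]
    return AdjustedPvalues("holm", p, adj)


def _check_pmat(p: np.ndarray, Pmat: np.ndarray) -> np.ndarray:
    Pmat = np.asarray(Pmat, dtype=float)
    if Pmat.ndim != 2 or Pmat.shape[1] != p.size:
        raise ValueError(
            f"resample p-value matrix must be (B, {p.size}); got {Pmat.shape}"
        )
    return Pmat


def minp_adjust(p, Pmat) -> AdjustedPvalues:
    """Westfall-Young single-step minP.

    adjusted_w = share of resamples whose minimum p-value (over all W tests)
    is <= p_w; the resamples must have been generated under the global null.
    """
    p = _as_p(p)
    Pmat = _check_pmat(p, Pmat)
    row_min = Pmat.min(axis=1)                         # (B,)
    adj = (row_min[:, None] <= p[None, :]).mean(axis=0)
    return AdjustedPvalues("minp", p, adj)


def wstep_adjust(p, Pmat) -> AdjustedPvalues:
    """Westfall-Young step-down (Wstep), uniformly more powerful than minP.

    With observed p-values ordered ascending, step i uses the minimum of each
    resample's p-values over the hypotheses at observed rank >= i; adjusted
    values are monotonized by a running maximum and unsorted.
    """
    p = _as_p(p)
    Pmat = _check_pmat(p, Pmat)
    order = np.argsort(p, kind="stable")
    # successive minima over suffixes of the observed ordering
    q = np.minimum.accumulate(Pmat[:, order[::-1]], axis=1)[:, ::-1]  # (B, W)
    adj_sorted = (q <= p[order][None, :]).mean(axis=0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return AdjustedPvalues("wstep", p, adj)


def romano_stepdown(absT, Tmat, alpha_W: float = 0.05) -> RomanoResult:
    """Romano-Wolf step-down using centered resampled statistics.

    Iterate: over the active (not yet rejected) set, take the empirical
    1 - alpha_W quantile (inverse-CDF convention) of the B row-maxima of
    |Tmat| restricted to the active set; reject every active hypothesis with
    |T_w| strictly above it; stop when a pass rejects nothing. Critical
    values are non-increasing across steps.
    """
    absT = np.asarray(absT, dtype=float)
    Tmat = np.abs(np.asarray(Tmat, dtype=float))
    W = absT.size
    if W == 0:
        return RomanoResult(np.zeros(0, bool), [], [], alpha_W)
    if Tmat.ndim != 2 or Tmat.shape[1] != W:
        raise ValueError(f"Tmat must be (B, {W}); got {Tmat.shape}")
    B = Tmat.shape[0]
    k = max(int(np.ceil((1.0 - alpha_W) * B)), 1) - 1
    rejected = np.zeros(W, dtype=bool)
    crit: list[float] = []
    steps: list[list[int]] = []
    while not rejected.all():
        active = ~rejected
        maxima = Tmat[:, active].max(axis=1)
        c = float(np.sort(maxima)[k])
        new = active & (absT > c)
        crit.append(c)
        if not new.any():
            break
        steps.append(np.flatnonzero(new).tolist())
        rejected |= new
    return RomanoResult(rejected, crit, steps, alpha_W)


def global_test_from_fwer(result, alpha_W: float = 0.05) -> bool:
    """Reject the global null iff the procedure makes >= 1 familywise rejection."""
    return n_familywise_rejections(result, alpha_W) > 0


def n_familywise_rejections(result, alpha_W: float = 0.05) -> int:
    if isinstance(result, RomanoResult):
        return int(result.rejected.sum())
    return int(result.rejections(alpha_W).sum())
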