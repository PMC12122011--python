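"""Residual-row resampling under the global null for shared-design OLS.

The valid scheme fixes the design matrix and sets each resampled outcome row
to the fitted values plus a residual row drawn (with replacement) jointly
across all W outcomes, preserving both the outcome-covariate correlations and
the residual correlations between outcomes. Resampled test statistics are
centered at the original estimates,

    T(j)_w = (beta(j)_w - beta_w) / (sigma(j)_w * sqrt([(X'X)^{-1}]_ee)),

so the resamples behave as if every null hypothesis held, regardless of the
data-generating truth. A "residual-only" variant uses the resampled residual
rows alone as outcomes with uncentered statistics; for OLS the two variants
give identical |T(j)| for the same index draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Dataset
from .ols import FitResult, fit_ols_many

__all__ = [
    "ResampleDraws",
    "resample_rows",
    "centered_statistics",
    "run_resampling",
    "empirical_cdf",
]

_VARIANTS = ("centered", "residual-only")


@dataclass
class ResampleDraws:
    """B resampled statistic/p-value vectors and their rejection counts."""

    Tmat: np.ndarray        # (B, W) centered (or residual-only) statistics
    Pmat: np.ndarray        # (B, W) p-values on the t(N - C) reference
    counts: np.ndarray      # (B,) theta-hat(j) at `alpha`
    alpha: float
    B: int
    seed: int | None
    variant: str
    df: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (self.B,) or self.Tmat.shape[0] != self.B:
            raise ValueError("inconsistent B across draw matrices")

    @property
    def W(self) -> int:
        return self.Tmat.shape[1]


def resample_rows(
    fit: FitResult,
    data: Dataset,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    negate_residuals: bool = False,
) -> np.ndarray:
    """One resampled outcome matrix Y(j): fitted values + resampled residual rows.

    Indices are drawn i.i.d. uniform on the N rows and shared across all W
    outcomes, so whole residual rows move together. ``negate_residuals``
    adds the sign-flipped residual row instead (an equivalent convention for
    two-sided inference; see module docs). The design matrix is untouched.
    """
    N = data.n_obs
    if indices is None:
        indices = rng.integers(0, N, size=N)
    R = fit.residuals[indices]
    if negate_residuals:
        R = -R
    return fit.fitted + R


def centered_statistics(fit_orig: FitResult, fit_resamp: FitResult) -> np.ndarray:
    """Centered statistics T(j) = (beta(j) - beta) / (sigma(j) * sqrt(d_ee)).

    The denominator reuses the fixed design's (X'X)^{-1}; a degenerate
    resample with sigma(j) = 0 yields a statistic of 0 (a non-rejection)
    with a warning.
    """
    e = fit_orig.exposure_index
    d = np.sqrt(fit_orig.xtx_inv[e, e])
    num = fit_resamp.beta - fit_orig.beta
    denom = fit_resamp.sigma * d
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} resampled outcome(s) had zero residual scale; "
            "their statistics are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=~zero)
    # exact-zero numerator beats any denominator, including 0/0
    out[num == 0.0] = 0.0
    return out


def _draw_indices(rng: np.random.Generator, B: int, N: int) -> np.ndarray:
    # j-major order: row j holds the j-th resample's N index draws
    return rng.integers(0, N, size=(B, N))


def run_resampling(
    data: Dataset,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    variant: str = "centered",
    fit: FitResult | None = None,
    rng: np.random.Generator | None = None,
    indices: np.ndarray | None = None,
    negate_residuals: bool = False,
    reference: str = "t",
    chunk: int = 128,
) -> ResampleDraws:
    """Generate B global-null resamples and their rejection counts.

    Refitting exploits the fixed design: with Q an orthonormal basis for
    col(X), the resample's residual sum of squares is ||R||^2 - ||Q'R||^2 and
    beta(j) - beta is the exposure row of (X'X)^{-1}X' applied to the drawn
    residual rows R. This is an algebraic identity with naive per-resample
    refitting (asserted in tests), and makes the loop a handful of small
    matrix products per chunk of resamples.

    ``variant="residual-only"`` uses Y(j) = resampled residual rows with
    uncentered statistics (the Westfall-Young OLS scheme); identical |T(j)|
    to the centered variant for the same draws.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if fit is None:
        fit = fit_ols_many(data)
    if rng is None:
        rng = np.random.default_rng(seed)
    N, W = data.n_obs, data.n_outcomes
    e = fit.exposure_index
    if indices is None:
        indices = _draw_indices(rng, B, N)
    else:
        indices = np.asarray(indices)
        if indices.shape != (B, N):
            raise ValueError(f"indices must have shape {(B, N)}")

    a_e = fit.projector[e]                         # (N,) exposure row of (X'X)^{-1}X'
    Q, _ = np.linalg.qr(data.X)                    # (N, C) orthonormal basis
    d = np.sqrt(fit.xtx_inv[e, e])
    df = fit.df

    Tmat = np.empty((B, W))
    warned = False
    for start in range(0, B, chunk):
        idx = indices[start : start + chunk]       # (m, N)
        R = fit.residuals[idx]                     # (m, N, W) resampled residual rows
        if negate_residuals:
            R = -R
        # both variants share residuals (I - H)(Yhat + R) = (I - H)R
        num = np.einsum("n,mnw->mw", a_e, R)       # beta(j) - beta  (or beta(j) itself)
        rss = np.einsum("mnw,mnw->mw", R, R) - np.einsum(
            "mnw,mnw->mw", QtR := np.einsum("nc,mnw->mcw", Q, R), QtR
        )
        rss = np.maximum(rss, 0.0)
        sigma_j = np.sqrt(rss / df)
        denom = sigma_j * d
        zero = denom == 0.0
        if zero.any() and not warned:
            warnings.warn(
                "degenerate resample(s) with zero residual scale; statistics set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        T = np.zeros_like(num)
        np.divide(num, denom, out=T, where=~zero)
        T[num == 0.0] = 0.0
        Tmat[start : start + chunk] = T

    if reference == "t":
        Pmat = 2.0 * stats.t.sf(np.abs(Tmat), df)
    elif reference == "normal":
        Pmat = 2.0 * stats.norm.sf(np.abs(Tmat))
    else:
        raise ValueError("reference must be 't' or 'normal'")
    counts = (Pmat < alpha).sum(axis=1)
    return ResampleDraws(
        Tmat=Tmat, Pmat=Pmat, counts=counts, alpha=alpha, B=B,
        seed=seed, variant=variant, df=df,
    )


def empirical_cdf(draws, r: int) -> float:
    """Empirical CDF of the resampled rejection counts at integer r.

    Returns (1/B) * #{j : theta-hat(j) <= r}; non-decreasing in r and equal
    to 1 at r = W. ``draws`` may be a ResampleDraws or a bare count array.
    """
    if r < 0:
        raise ValueError("r must be a nonnegative integer")
    counts = draws.counts if hasattr(draws, "counts") else np.asarray(draws)
    return float(np.count_nonzero(counts <= r)) / counts.size
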