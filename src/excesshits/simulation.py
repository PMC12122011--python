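"""Monte-Carlo study of the metrics under equicorrelated normal outcomes.

Data model: (X, Y1..YW) jointly multivariate standard normal with unit
variances, pairwise outcome correlation rho_YY, and exposure-outcome
correlation rho_XY for the first q*W outcomes (0 for the rest). Each
replicate generates a dataset, fits the W shared-design regressions, counts
observed rejections, resamples under the global null, and evaluates the
count-based metrics alongside the five FWER comparators, all from the same
resample draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fwer
from .data import Dataset
from .metrics import compute_global_metrics
from .ols import count_rejections, fit_ols_many
from .resampling import run_resampling

__all__ = [
    "SimScenario",
    "SimSummary",
    "make_correlation",
    "generate_dataset",
    "run_scenario",
    "summarize_grid",
]

log = logging.getLogger(__name__)

ALL_METHODS = ("bonferroni", "holm", "minp", "wstep", "romano")


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation grid."""

    W: int = 40
    N: int = 1000
    rho_XY: float = 0.0
    rho_YY: float = 0.0
    q: float = 0.0
    alpha: float = 0.05
    alpha_W: float = 0.05
    nsim: int = 100
    B: int = 500
    seed: int = 0
    variant: str = "centered"

    @property
    def n_false_nulls(self) -> int:
        k = self.q * self.W
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"q*W = {k} is not an integer (q={self.q}, W={self.W})")
        return int(round(k))


def make_correlation(W: int, rho_XY: float, rho_YY: float, q: float) -> np.ndarray:
    """(W+1) x (W+1) correlation matrix; row/column 0 is the exposure X.

    Entry (X, Yw) is rho_XY for the first q*W outcomes and 0 otherwise; all
    outcome pairs share correlation rho_YY. Raises if the matrix is not
    positive semidefinite (smallest eigenvalue < -1e-8), mirroring the
    exclusion of such parameter combinations from the study grid.
    """
    k = q * W
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"q*W = {k} is not an integer")
    k = int(round(k))
    C = np.full((W + 1, W + 1), rho_YY)
    np.fill_diagonal(C, 1.0)
    C[0, 1:] = C[1:, 0] = 0.0
    C[0, 1 : 1 + k] = C[1 : 1 + k, 0] = rho_XY
    lam_min = float(np.linalg.eigvalsh(C).min())
    if lam_min < -1e-8:
        raise ValueError(
            f"correlation matrix not positive semidefinite "
            f"(min eigenvalue {lam_min:.3g}) for W={W}, rho_XY={rho_XY}, "
            f"rho_YY={rho_YY}, q={q}"
        )
    return C


def generate_dataset(scenario: SimScenario, rng: np.random.Generator) -> Dataset:
    """Draw N i.i.d. rows from the scenario's multivariate standard normal."""
    C = make_correlation(scenario.W, scenario.rho_XY, scenario.rho_YY, scenario.q)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    Z = rng.standard_normal((scenario.N, scenario.W + 1)) @ L.T
    x = Z[:, 0]
    return Dataset(
        X=np.column_stack([np.ones(scenario.N), x]),
        Y=Z[:, 1:],
        exposure_index=1,
        exposure_name="X",
    )


@dataclass
class SimSummary:
    """Per-replicate records and aggregated summaries for one scenario."""

    scenario: SimScenario
    replicates: pd.DataFrame
    summary: pd.Series
    n_failed: int = 0
    methods: tuple[str, ...] = field(default_factory=tuple)


def _replicate(scenario: SimScenario, seed: np.random.SeedSequence, methods):
    rng = np.random.default_rng(seed)
    data = generate_dataset(scenario, rng)
    fit = fit_ols_many(data)
    theta_hat = count_rejections(fit, scenario.alpha)
    draws = run_resampling(
        data,
        alpha=scenario.alpha,
        B=scenario.B,
        rng=rng,
        variant=scenario.variant,
        fit=fit,
    )
    gm = compute_global_metrics(theta_hat, draws, alpha_W=scenario.alpha_W)
    k = scenario.n_false_nulls
    rec = {
        "theta_hat": theta_hat,
        "mean_count": float(draws.counts.mean()),
        "lo": gm.interval[0],
        "hi": gm.interval[1],
        "excess": gm.excess_hits,
        "fw_rejections": gm.fw_rejections,
        "global_p": gm.global_p,
        "count_reject": gm.global_p <= scenario.alpha_W,
        "n_true_null_rej": int(np.count_nonzero(fit.p[k:] < scenario.alpha)),
    }
    for m in methods:
        if m == "bonferroni":
            res = fwer.bonferroni(fit.p)
        elif m == "holm":
            res = fwer.holm(fit.p)
        elif m == "minp":
            res = fwer.minp_adjust(fit.p, draws.Pmat)
        elif m == "wstep":
            res = fwer.wstep_adjust(fit.p, draws.Pmat)
        elif m == "romano":
            res = fwer.romano_stepdown(np.abs(fit.t), draws.Tmat, scenario.alpha_W)
        else:
            raise ValueError(f"unknown method {m!r}")
        n = fwer.n_familywise_rejections(res, scenario.alpha_W)
        rec[f"{m}_n_rej"] = n
        rec[f"{m}_reject"] = n > 0
    return rec


def run_scenario(
    scenario: SimScenario, methods: tuple[str, ...] = ALL_METHODS
) -> SimSummary:
    """Run the scenario's nsim replicates and aggregate.

    A master SeedSequence spawns one child per replicate, so runs are
    reproducible and order-independent. Replicates that fail (e.g. a
    degenerate draw) are logged and excluded, with the count reported.
    """
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.nsim)
    records, n_failed = [], 0
    for i, child in enumerate(children):
        try:
            records.append(_replicate(scenario, child, methods))
        except Exception:  # pragma: no cover - defensive
            n_failed += 1
            log.exception("replicate %d of scenario %s failed; excluded", i, scenario)
    reps = pd.DataFrame.from_records(records)
    nsim = len(reps)
    agg = {
        "mean_theta_hat": reps["theta_hat"].mean(),
        "se_theta_hat": reps["theta_hat"].std(ddof=1) / np.sqrt(nsim),
        "mean_count": reps["mean_count"].mean(),
        "se_mean_count": reps["mean_count"].std(ddof=1) / np.sqrt(nsim),
        "mean_lo": reps["lo"].mean(),
        "mean_hi": reps["hi"].mean(),
        "se_hi": reps["hi"].std(ddof=1) / np.sqrt(nsim),
        "mean_excess": reps["excess"].mean(),
        "mean_fw_rejections": reps["fw_rejections"].mean(),
        "count_reject_rate": reps["count_reject"].mean(),
        "nsim": nsim,
    }
    agg["se_count_reject_rate"] = np.sqrt(
        agg["count_reject_rate"] * (1 - agg["count_reject_rate"]) / nsim
    )
    for m in methods:
        rate = reps[f"{m}_reject"].mean()
        agg[f"{m}_reject_rate"] = rate
        agg[f"se_{m}_reject_rate"] = np.sqrt(rate * (1 - rate) / nsim)
        agg[f"{m}_mean_n_rej"] = reps[f"{m}_n_rej"].mean()
    return SimSummary(
        scenario=scenario,
        replicates=reps,
        summary=pd.Series(agg),
        n_failed=n_failed,
        methods=tuple(methods),
    )


_SCENARIO_KEYS = ("W", "N", "rho_XY", "rho_YY", "q", "alpha", "alpha_W", "nsim", "B", "seed")


def summarize_grid(summaries: list[SimSummary]) -> pd.DataFrame:
    """Tidy long-format table: one row per scenario x method.

    The count-based global test appears as method "global_count" with its
    familywise rejection count max(0, excess hits).
    """
    rows = []
    for s in summaries:
        base = {k: getattr(s.scenario, k) for k in _SCENARIO_KEYS}
        rows.append(
            base
            | {
                "method": "global_count",
                "reject_rate": s.summary["count_reject_rate"],
                "se_reject_rate": s.summary["se_count_reject_rate"],
                "mean_n_rejected": s.summary["mean_fw_rejections"],
                "mean_theta_hat": s.summary["mean_theta_hat"],
                "mean_lo": s.summary["mean_lo"],
                "mean_hi": s.summary["mean_hi"],
            }
        )
        for m in s.methods:
            rows.append(
                base
                | {
                    "method": m,
                    "reject_rate": s.summary[f"{m}_reject_rate"],
                    "se_reject_rate": s.summary[f"se_{m}_reject_rate"],
                    "mean_n_rejected": s.summary[f"{m}_mean_n_rej"],
                    "mean_theta_hat": s.summary["mean_theta_hat"],
                    "mean_lo": s.summary["mean_lo"],
                    "mean_hi": s.summary["mean_hi"],
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        dup = df.duplicated(subset=[*_SCENARIO_KEYS, "method"])
        if dup.any():
            raise ValueError("duplicate scenario x method rows in grid")
    return df


def expand_grid(grid: dict, nsim: int, B: int, seed: int) -> list[SimScenario]:
    """Full-factorial scenarios from lists of parameter values, pruning
    combinations whose correlation matrix is not positive semidefinite.

    Returns the kept scenarios; pruned combinations are reported via the
    second element of the tuple when ``return_pruned`` semantics are needed —
    see :func:`grid_with_manifest`.
    """
    return grid_with_manifest(grid, nsim, B, seed)[0]


def grid_with_manifest(grid: dict, nsim: int, B: int, seed: int):
    from itertools import product

    keys = ("W", "N", "rho_XY", "rho_YY", "q", "alpha")
    lists = [np.atleast_1d(grid.get(k, getattr(SimScenario, k))) for k in keys]
    kept, pruned = [], []
    for i, combo in enumerate(product(*lists)):
        params = dict(zip(keys, combo))
        params = {k: (int(v) if k in ("W", "N") else float(v)) for k, v in params.items()}
        try:
            make_correlation(params["W"], params["rho_XY"], params["rho_YY"], params["q"])
        except ValueError as err:
            pruned.append(params | {"reason": str(err)})
            continue
        kept.append(SimScenario(nsim=nsim, B=B, seed=seed + i, **params))
    return kept, pruned
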