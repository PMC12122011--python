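"""Validated container for a shared-design regression dataset.

One exposure is tested against W outcomes, all regressed on the same design
matrix (intercept, exposure, optional adjusted covariates). The design is
treated as fixed throughout: the resampling algorithms in
:mod:`excesshits.resampling` never touch it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = piv[diag <= tol] if diag.size else piv
    return [names[i] for i in sorted(bad)]


@dataclass
class Dataset:
    """Fixed design matrix paired with an outcome matrix.

    Parameters
    ----------
    X : (N, C) array
        Design matrix. Column 0 must be a constant intercept of ones; one
        column (``exposure_index``) is the exposure whose coefficient is
        tested in every outcome model.
    Y : (N, W) array
        Outcome matrix, one column per tested outcome.
    """

    X: np.ndarray
    Y: np.ndarray
    exposure_index: int = 1
    exposure_name: str = "exposure"
    covariate_names: list[str] = field(default_factory=list)
    outcome_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        N, C = self.X.shape
        if self.Y.shape[0] != N:
            raise ValueError(f"X has {N} rows but Y has {self.Y.shape[0]}")
        if C < 2:
            raise ValueError("design must contain at least an intercept and the exposure")
        if N <= C:
            raise ValueError(f"need more observations than design columns (N={N}, C={C})")
        if self.Y.shape[1] < 1:
            raise ValueError("need at least one outcome")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError(
                "missing values are not supported: resampling requires a complete, "
                "fixed design; impute or drop incomplete rows explicitly before loading"
            )
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("column 0 of X must be a constant intercept of ones")
        if not (1 <= self.exposure_index < C):
            raise ValueError(f"exposure_index {self.exposure_index} outside design")
        if not self.outcome_names:
            self.outcome_names = [f"Y{w + 1}" for w in range(self.Y.shape[1])]
        if len(self.outcome_names) != self.Y.shape[1]:
            raise ValueError("outcome_names length does not match Y")
        if np.linalg.matrix_rank(self.X) < C:
            names = ["intercept", self.exposure_name] + list(self.covariate_names)
            names += [f"X{c}" for c in range(len(names), C)]
            bad = _collinear_columns(self.X, names[:C])
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_design(self) -> int:
        return self.X.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        exposure: str,
        outcomes: list[str],
        covariates: list[str] | None = None,
        center_covariates: bool = False,
    ) -> "Dataset":
        """Build a Dataset from a tidy DataFrame (rows = subjects).

        ``center_covariates`` mean-centers the exposure and covariate columns;
        the exposure's coefficient, t statistic and p-value are invariant to
        this, so it is off by default.
        """
        covariates = list(covariates or [])
        roles = [exposure, *outcomes, *covariates]
        missing = [c for c in roles if c not in df.columns]
        if missing:
            raise KeyError(
                f"columns {missing} not found; available: {sorted(df.columns)}"
            )
        if len(set(roles)) != len(roles):
            raise ValueError("exposure, outcome and covariate roles must be disjoint")
        sub = df[roles]
        if not all(np.issubdtype(t, np.number) for t in sub.dtypes):
            bad = [c for c, t in sub.dtypes.items() if not np.issubdtype(t, np.number)]
            raise ValueError(f"non-numeric columns in roles: {bad}")
        if sub.isna().any().any():
            rows = sub.index[sub.isna().any(axis=1)].tolist()
            cols = sub.columns[sub.isna().any(axis=0)].tolist()
            raise ValueError(f"missing values in rows {rows[:10]} (columns {cols})")
        N = len(df)
        Xcols = [np.ones(N), sub[exposure].to_numpy(float)]
        Xcols += [sub[c].to_numpy(float) for c in covariates]
        X = np.column_stack(Xcols)
        if center_covariates:
            X[:, 1:] = X[:, 1:] - X[:, 1:].mean(axis=0)
        return cls(
            X=X,
            Y=sub[outcomes].to_numpy(float),
            exposure_index=1,
            exposure_name=exposure,
            covariate_names=covariates,
            outcome_names=list(outcomes),
        )
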