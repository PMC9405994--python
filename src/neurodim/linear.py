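"""Multivariate multiple regression: shared predictors, several outcomes.

With a common design matrix, multivariate OLS coefficients coincide with
equation-by-equation OLS, so the fit is computed once from the normal
equations and per-outcome diagnostics (R-squared, overall F, standardized
betas, per-predictor t and two-tailed p) are derived per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RankDeficiencyError, SchemaError


@dataclass
class OutcomeFit:
    """Diagnostics for one outcome column."""

    outcome: str
    intercept: float
    coefficients: Dict[str, float]          # raw-unit B
    std_coefficients: Dict[str, float]      # standardized beta
    r_squared: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    t_values: Dict[str, float]
    p_values: Dict[str, float]
    residual_variance: float


@dataclass
class RegressionFit:
    predictors: List[str]
    outcomes: List[str]
    fits: Dict[str, OutcomeFit]
    n_cases: int
    _coef_matrix: np.ndarray = field(repr=False, default=None)  # (k+1) x m incl intercept

    def to_jsonable(self) -> dict:
        out = {}
        for name, f in self.fits.items():
            out[name] = {
                "intercept": f.intercept,
                "B": f.coefficients,
                "beta": f.std_coefficients,
                "r_squared": f.r_squared,
                "F": f.f_statistic,
                "df": [f.df1, f.df2],
                "p": f.p_value,
                "t": f.t_values,
                "p_per_predictor": f.p_values,
            }
        return {"n_cases": self.n_cases, "predictors": self.predictors, "outcomes": out}


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def fit_mvreg(X: pd.DataFrame, Y: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares of every column of Y on the columns of X.

    Raises :class:`RankDeficiencyError` (naming the offending columns) if
    the design matrix is rank deficient or numerically near-singular.
    """
    n, k = X.shape
    if n <= k + 1:
        raise SchemaError(f"need n > k + 1 cases (got n={n}, k={k})")
    D = _design(X)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1] or np.linalg.cond(D.T @ D) > 1e12:
        offenders = _collinear_columns(X)
        raise RankDeficiencyError(offenders)

    Ymat = Y.to_numpy(dtype=float)
    XtX = D.T @ D
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ D.T @ Ymat  # (k+1) x m
    fitted = D @ coef
    resid = Ymat - fitted

    df1, df2 = k, n - k - 1
    x_sd = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    diag = np.diag(XtX_inv)

    fits: Dict[str, OutcomeFit] = {}
    for j, outcome in enumerate(Y.columns):
        y = Ymat[:, j]
        ss_res = float(resid[:, j] @ resid[:, j])
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        sigma2 = ss_res / df2
        se = np.sqrt(sigma2 * diag)  # incl. intercept at position 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_vals = coef[:, j] / se
        p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df2)
        y_sd = y.std(ddof=1)
        betas = coef[1:, j] * x_sd / y_sd if y_sd > 0 else np.zeros(k)
        F, _d1, _d2, p = overall_f_test(r2, n, k)
        fits[outcome] = OutcomeFit(
            outcome=outcome,
            intercept=float(coef[0, j]),
            coefficients={c: float(coef[i + 1, j]) for i, c in enumerate(X.columns)},
            std_coefficients={c: float(betas[i]) for i, c in enumerate(X.columns)},
            r_squared=float(r2),
            f_statistic=F,
            df1=df1,
            df2=df2,
            p_value=p,
            t_values={c: float(t_vals[i + 1]) for i, c in enumerate(X.columns)},
            p_values={c: float(p_vals[i + 1]) for i, c in enumerate(X.columns)},
            residual_variance=float(sigma2),
        )
    return RegressionFit(
        predictors=list(X.columns),
        outcomes=list(Y.columns),
        fits=fits,
        n_cases=n,
        _coef_matrix=coef,
    )


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    """Greedy scan for columns linearly dependent on the preceding ones."""
    cols, offenders = [], []
    base = [np.ones(len(X))]
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        B = np.column_stack(base)
        resid = v - B @ np.linalg.lstsq(B, v, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(v)):
            offenders.append(c)
        else:
            base.append(v)
            cols.append(c)
    return offenders or list(X.columns)


def overall_f_test(r_squared: float, n: int, k: int):
    """Overall model F from R-squared: F = (R2/k) / ((1-R2)/(n-k-1)).

    Returns (F, df1, df2, upper-tail p). R-squared of exactly 1 yields an
    infinite F and p = 0.
    """
    if not (0.0 <= r_squared <= 1.0):
        raise ValueError("r_squared must lie in [0, 1]")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    df1, df2 = k, n - k - 1
    if r_squared >= 1.0:
        return float("inf"), df1, df2, 0.0
    F = (r_squared / df1) / ((1.0 - r_squared) / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def predict(fit: RegressionFit, X: pd.DataFrame) -> pd.DataFrame:
    """Affine prediction for each outcome using the fitted coefficients."""
    missing = [c for c in fit.predictors if c not in X.columns]
    if missing:
        raise SchemaError(f"predictor columns missing: {', '.join(missing)}")
    D = _design(X[fit.predictors])
    preds = D @ fit._coef_matrix
    return pd.DataFrame(preds, columns=fit.outcomes, index=X.index)
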