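"""Confirmatory factor analysis by maximum likelihood, with factor scores.

Two measurement models are supported over the nine domain scores: a
correlated-factors model (internalising + externalising, free correlation)
and a single-factor model (the p-factor).  Identification is by unit factor
variance, so the factor covariance matrix is a correlation matrix.  The
fitting machinery is generic over the indicator set, which also serves the
small closed-form test models.

The discrepancy minimised is the normal-theory ML function

    F_ML(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

with Sigma(theta) = Lambda Phi Lambda' + Psi and Psi diagonal but
*unconstrained in sign*: a negative unique variance (Heywood case) is a
legitimate, observable outcome reported through per-indicator flags, never
silently clamped.  When the sample matrix S is not positive definite the ML
function is undefined (log|S| does not exist); the fit then falls back to
the unweighted least-squares discrepancy ``0.5 * ||Sigma - S||_F^2``, which
shares the exact-fit solution for just-identified models, and records the
estimator used.

Factor scores use the regression method,
``fhat = Phi Lambda' Sigma^-1 (x - xbar)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigError, HeywoodError, SchemaError, SingularCovarianceError
from .synthetic import DOMAIN_COLUMNS, default_loading_pattern


@dataclass
class ModelSpec:
    """A measurement-model layout: which indicator loads on which factor.

    The two standard specs cover the nine psychopathology domains; ad-hoc
    specs over other indicator sets are allowed for small test models.
    """

    name: str
    factors: List[str]
    pattern: Dict[str, str]
    correlated: bool = True

    def validate(self) -> None:
        if not self.pattern:
            raise ConfigError("pattern must assign at least one indicator")
        unknown = set(self.pattern.values()) - set(self.factors)
        if unknown:
            raise ConfigError(f"pattern references unknown factors: {sorted(unknown)}")
        if len(set(self.factors)) != len(self.factors):
            raise ConfigError("factor names must be unique")
        # the standard psychopathology models must cover all nine domains
        if set(self.pattern) & set(DOMAIN_COLUMNS) and set(self.pattern) != set(
            DOMAIN_COLUMNS
        ):
            missing = set(DOMAIN_COLUMNS) - set(self.pattern)
            raise ConfigError(
                f"domain models must assign all 9 domains (missing: {sorted(missing)})"
            )

    @property
    def indicators(self) -> List[str]:
        return list(self.pattern.keys())

    @property
    def n_indicators(self) -> int:
        return len(self.pattern)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def n_free_parameters(self) -> int:
        k = self.n_factors
        n_corr = k * (k - 1) // 2 if self.correlated else 0
        return 2 * self.n_indicators + n_corr

    def degrees_of_freedom(self) -> int:
        p = self.n_indicators
        return p * (p + 1) // 2 - self.n_free_parameters()


def correlated_factors_spec() -> ModelSpec:
    pattern = {dom: fac for dom, (fac, _lam) in default_loading_pattern().items()}
    pattern = {dom: pattern[dom] for dom in DOMAIN_COLUMNS}  # canonical order
    return ModelSpec(
        name="correlated_factors",
        factors=["internalising", "externalising"],
        pattern=pattern,
        correlated=True,
    )


def single_factor_spec() -> ModelSpec:
    return ModelSpec(
        name="single_factor",
        factors=["p"],
        pattern={dom: "p" for dom in DOMAIN_COLUMNS},
        correlated=False,
    )


@dataclass
class FactorFit:
    """Result of one CFA estimation."""

    spec: ModelSpec
    loadings: Dict[str, float]
    uniquenesses: Dict[str, float]
    factor_covariance: np.ndarray  # unit diagonal; correlation matrix
    discrepancy: float
    chi_square: float
    df: int
    n_cases: int
    converged: bool
    heywood: Dict[str, bool]
    estimator: str  # "ml" or "uls"
    domain_order: List[str] = field(default_factory=list)

    @property
    def any_heywood(self) -> bool:
        return any(self.heywood.values())

    def lambda_matrix(self) -> np.ndarray:
        lam = np.zeros((len(self.domain_order), self.spec.n_factors))
        for i, dom in enumerate(self.domain_order):
            j = self.spec.factors.index(self.spec.pattern[dom])
            lam[i, j] = self.loadings[dom]
        return lam

    def psi_vector(self) -> np.ndarray:
        return np.array([self.uniquenesses[d] for d in self.domain_order])

    def to_jsonable(self) -> dict:
        return {
            "model": self.spec.name,
            "estimator": self.estimator,
            "loadings": self.loadings,
            "uniquenesses": self.uniquenesses,
            "factor_covariance": self.factor_covariance.tolist(),
            "discrepancy": self.discrepancy,
            "chi_square": self.chi_square,
            "df": self.df,
            "n_cases": self.n_cases,
            "converged": self.converged,
            "heywood": self.heywood,
        }


def implied_covariance(fit: FactorFit, spec: ModelSpec | None = None) -> np.ndarray:
    """The model-implied covariance Lambda Phi Lambda' + Psi (symmetric)."""
    spec = spec or fit.spec
    lam = fit.lambda_matrix()
    phi = np.asarray(fit.factor_covariance, dtype=float)
    if phi.shape != (spec.n_factors, spec.n_factors):
        raise ConfigError("factor covariance dimension does not match spec")
    sigma = lam @ phi @ lam.T + np.diag(fit.psi_vector())
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# estimation internals

def _unpack(theta, p, k, correlated):
    lam = theta[:p]
    psi = theta[p : 2 * p]
    phi = np.eye(k)
    if correlated:
        off = theta[2 * p :]
        idx = np.triu_indices(k, 1)
        phi[idx] = off
        phi[(idx[1], idx[0])] = off
    return lam, psi, phi


def _sigma_of(theta, load_col, p, k, correlated):
    lam_v, psi, phi = _unpack(theta, p, k, correlated)
    lam = np.zeros((p, k))
    lam[np.arange(p), load_col] = lam_v
    return lam, psi, phi, lam @ phi @ lam.T + np.diag(psi)


_BIG = 1e8


def _objective(theta, S, load_col, p, k, correlated, estimator):
    lam, psi, phi, sigma = _sigma_of(theta, load_col, p, k, correlated)
    if estimator == "uls":
        diff = sigma - S
        f = 0.5 * np.sum(diff * diff)
        g_sigma = diff
    else:
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            # outside the PD cone: steep penalty keeps the search inside
            min_eig = float(np.linalg.eigvalsh(sigma).min())
            return _BIG * (1.0 + abs(min_eig)), np.zeros_like(theta)
        sigma_inv = np.linalg.inv(sigma)
        _sign_s, logdet_s = np.linalg.slogdet(S)
        f = logdet + float(np.trace(S @ sigma_inv)) - logdet_s - p
        g_sigma = sigma_inv - sigma_inv @ S @ sigma_inv

    g_lam_full = 2.0 * g_sigma @ lam @ phi
    g_lam = g_lam_full[np.arange(p), load_col]
    g_psi = np.diag(g_sigma).copy()
    grads = [g_lam, g_psi]
    if correlated:
        g_phi = lam.T @ g_sigma @ lam
        idx = np.triu_indices(k, 1)
        grads.append(2.0 * g_phi[idx])
    return f, np.concatenate(grads)


def sample_covariance(table: pd.DataFrame, indicators: List[str]):
    """Sample covariance (ddof=1) over the indicator columns, plus n."""
    missing = [c for c in indicators if c not in table.columns]
    if missing:
        raise SchemaError(f"domain table missing columns: {', '.join(missing)}")
    X = table[indicators].to_numpy(dtype=float)
    return np.cov(X, rowvar=False, ddof=1), X.shape[0]


def _coerce_covariance(domain_table, indicators, n_cases):
    """Accept either a case table or a precomputed covariance matrix."""
    p = len(indicators)
    if isinstance(domain_table, np.ndarray):
        if domain_table.shape != (p, p):
            raise SchemaError(f"covariance matrix must be {p}x{p}")
        if n_cases is None:
            raise ConfigError("n_cases required when fitting a covariance matrix")
        return np.asarray(domain_table, dtype=float), n_cases
    if isinstance(domain_table, pd.DataFrame) and list(domain_table.index) == list(
        domain_table.columns
    ) and len(domain_table) == p:
        if n_cases is None:
            raise ConfigError("n_cases required when fitting a covariance matrix")
        return domain_table.loc[indicators, indicators].to_numpy(dtype=float), n_cases
    return sample_covariance(domain_table, indicators)


def fit_cfa(
    domain_table,
    spec: ModelSpec,
    *,
    n_cases: int | None = None,
    max_restarts: int = 3,
) -> FactorFit:
    """Fit a measurement model to the indicator columns by ML.

    ``domain_table`` is a case-level DataFrame, or a precomputed covariance
    matrix (square DataFrame with matching index/columns, or ndarray), in
    which case ``n_cases`` must be supplied.  Returns ``converged=False``
    rather than raising when the optimizer stalls.
    """
    spec.validate()
    indicators = spec.indicators
    p = len(indicators)
    S, n = _coerce_covariance(domain_table, indicators, n_cases)

    if abs(np.linalg.det(S)) < 1e-300 or np.linalg.cond(S) > 1e12:
        raise SingularCovarianceError("sample covariance matrix is singular")

    eigvals = np.linalg.eigvalsh(S)
    estimator = "ml" if eigvals.min() > 1e-10 else "uls"

    k = spec.n_factors
    load_col = np.array(
        [spec.factors.index(spec.pattern[d]) for d in indicators], dtype=int
    )
    n_corr = k * (k - 1) // 2 if spec.correlated else 0
    scale = np.sqrt(np.diag(S))

    def start(jitter_rng=None):
        theta = np.concatenate(
            [0.7 * scale, 0.51 * np.diag(S), np.full(n_corr, 0.3)]
        )
        if jitter_rng is not None:
            theta = theta * (1.0 + jitter_rng.uniform(-0.2, 0.2, size=theta.size))
        return theta

    bounds = [(None, None)] * (2 * p) + [(-0.999, 0.999)] * n_corr

    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(max_restarts + 1):
        theta0 = start(None if attempt == 0 else rng)
        res = minimize(
            _objective,
            theta0,
            args=(S, load_col, p, k, spec.correlated, estimator),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.max(np.abs(res.jac)) < 1e-6:
            best = res
            break

    lam_v, psi, phi = _unpack(best.x.copy(), p, k, spec.correlated)
    # sign convention: majority-positive loadings per factor
    for j in range(k):
        mask = load_col == j
        if lam_v[mask].sum() < 0:
            lam_v[mask] = -lam_v[mask]
            for jj in range(k):
                if jj != j:
                    phi[j, jj] = -phi[j, jj]
                    phi[jj, j] = -phi[jj, j]

    loadings = {d: float(lam_v[i]) for i, d in enumerate(indicators)}
    uniquenesses = {d: float(psi[i]) for i, d in enumerate(indicators)}
    heywood = {d: bool(uniquenesses[d] <= 0.0) for d in indicators}
    f_val = float(max(best.fun, 0.0))
    df = spec.degrees_of_freedom()
    converged = bool(best.success and np.max(np.abs(best.jac)) < 1e-4)
    chi_square = float((n - 1) * f_val) if estimator == "ml" else float("nan")

    return FactorFit(
        spec=spec,
        loadings=loadings,
        uniquenesses=uniquenesses,
        factor_covariance=phi,
        discrepancy=f_val,
        chi_square=chi_square,
        df=df,
        n_cases=n,
        converged=converged,
        heywood=heywood,
        estimator=estimator,
        domain_order=indicators,
    )


def factor_scores(
    fit: FactorFit,
    spec: ModelSpec | None = None,
    domain_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regression-method factor scores, one column per factor.

    Scores are centred on the scoring sample's mean, so a case at the mean
    scores exactly zero on every factor.

    Raises
    ------
    HeywoodError
        if the fit contains a negative unique variance.
    """
    spec = spec or fit.spec
    if domain_table is None:
        raise ConfigError("domain_table is required")
    if fit.any_heywood:
        bad = sorted(d for d, flag in fit.heywood.items() if flag)
        raise HeywoodError(
            f"fit has Heywood cases (negative unique variance): {', '.join(bad)}"
        )
    missing = [c for c in fit.domain_order if c not in domain_table.columns]
    if missing:
        raise SchemaError(f"domain table missing columns: {', '.join(missing)}")
    X = domain_table[fit.domain_order].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    lam = fit.lambda_matrix()
    phi = np.asarray(fit.factor_covariance, dtype=float)
    sigma = implied_covariance(fit, spec)
    weights = phi @ lam.T @ np.linalg.inv(sigma)  # k x p
    scores = Xc @ weights.T
    return pd.DataFrame(scores, columns=spec.factors, index=domain_table.index)
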