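"""Maximum likelihood for the left-truncated normal regression.

Model: delta_i = z_i' beta + eps_i with eps_i ~ N(0, sigma^2) truncated on
the left so that delta_i >= 1 (Shephard distances are bounded below by one).
The log likelihood of an interior observation is

    -log sigma + log phi((delta_i - z_i'beta)/sigma)
               - log Phi((z_i'beta - 1)/sigma),

since P(delta_i >= 1) = Phi((z_i'beta - 1)/sigma). The score is available in
closed form, so the optimizer is quasi-Newton (BFGS) with the analytic
gradient, started from the OLS fit; sigma enters via log sigma to keep it
positive. As the truncation point is pushed to -infinity the estimator
collapses to OLS, which the tests exploit as a closed-form limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, InvalidArgumentError, NumericalError

_GRAD_TOL = 1e-6
_INTERIOR_TOL = 1e-9


@dataclass
class TruncRegFit:
    beta: np.ndarray
    sigma: float
    loglik: float
    n_used: int
    names: list[str]
    converged: bool
    grad_norm: float
    truncation: float

    def coef_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)


def _as_matrix(Z) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(float), list(Z.columns)
    Z = np.asarray(Z, float)
    return Z, [f"z{i}" for i in range(Z.shape[1])]


def truncreg_loglik(
    params: np.ndarray, delta: np.ndarray, Z: np.ndarray, truncation: float = 1.0
) -> float:
    """Log likelihood at params = (beta..., log sigma)."""
    beta, logs = params[:-1], params[-1]
    sigma = np.exp(logs)
    mu = Z @ beta
    r = (delta - mu) / sigma
    a = (mu - truncation) / sigma
    return float(
        np.sum(-logs + stats.norm.logpdf(r) - stats.norm.logcdf(a))
    )


def truncreg_score(
    params: np.ndarray, delta: np.ndarray, Z: np.ndarray, truncation: float = 1.0
) -> np.ndarray:
    """Analytic gradient of the log likelihood in (beta, log sigma)."""
    beta, logs = params[:-1], params[-1]
    sigma = np.exp(logs)
    mu = Z @ beta
    r = (delta - mu) / sigma
    a = (mu - truncation) / sigma
    lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))  # inverse Mills
    g_beta = Z.T @ (r / sigma - lam / sigma)
    g_logs = np.sum(-1.0 + r**2 + a * lam)
    return np.concatenate([g_beta, [g_logs]])


def truncreg_mle(
    delta,
    Z,
    truncation: float = 1.0,
    names: list[str] | None = None,
) -> TruncRegFit:
    """Fit the truncated regression on the interior observations.

    Observations at or below the truncation point (frontier DMUs, for which
    the estimated distance carries no likelihood information about the
    inefficiency distribution) are dropped; ``n_used`` records how many
    remain. ``truncation`` is exposed so tests can push it to -inf and
    recover the OLS limit.
    """
    delta = np.asarray(delta, float)
    Zmat, inferred = _as_matrix(Z)
    names = names or inferred
    if delta.shape[0] != Zmat.shape[0]:
        raise InvalidArgumentError("delta and Z have different lengths")
    interior = delta > truncation + _INTERIOR_TOL
    d, Zi = delta[interior], Zmat[interior]
    k = Zmat.shape[1]
    if d.shape[0] < k + 2:
        raise InsufficientDataError(
            f"{d.shape[0]} interior observations for {k} coefficients"
        )
    beta0, res0, *_ = np.linalg.lstsq(Zi, d, rcond=None)
    resid = d - Zi @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    x0 = np.concatenate([beta0, [np.log(s0)]])

    def nll(p):
        return -truncreg_loglik(p, d, Zi, truncation)

    def njac(p):
        return -truncreg_score(p, d, Zi, truncation)

    best = None
    for start in (x0, np.concatenate([beta0, [np.log(2 * s0)]])):
        res = optimize.minimize(
            nll, start, jac=njac, method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.linalg.norm(res.jac) < _GRAD_TOL:
            best = res
            break
    grad_norm = float(np.linalg.norm(best.jac))
    if grad_norm >= _GRAD_TOL:
        # polish with a derivative-free pass before giving up
        res = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        g = float(np.linalg.norm(njac(res.x)))
        if res.fun <= best.fun and g < grad_norm:
            best, grad_norm = res, g
    if not np.isfinite(best.fun) or grad_norm >= 1e-3:
        raise NumericalError(
            f"truncated-regression MLE did not converge "
            f"(gradient norm {grad_norm:.2e}, nll {best.fun:.4g})"
        )
    return TruncRegFit(
        beta=best.x[:-1].copy(),
        sigma=float(np.exp(best.x[-1])),
        loglik=float(-best.fun),
        n_used=int(d.shape[0]),
        names=list(names),
        converged=grad_norm < _GRAD_TOL,
        grad_norm=grad_norm,
        truncation=truncation,
    )


def sample_truncated(
    rng: np.random.Generator,
    mean: np.ndarray,
    sigma: float,
    lower: float = 1.0,
) -> np.ndarray:
    """Draw delta ~ N(mean, sigma^2) left-truncated at ``lower``.

    Inverse-CDF on the truncated region (bounded runtime however far the
    mean sits below the truncation point).
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    mean = np.asarray(mean, float)
    a = (lower - mean) / sigma
    u = rng.uniform(size=mean.shape)
    return mean + sigma * stats.truncnorm.ppf(u, a, np.inf)


def parametric_bootstrap(
    fit: TruncRegFit,
    Z,
    n_boot: int,
    rng: np.random.Generator,
    max_retries: int = 5,
) -> np.ndarray:
    """Bootstrap draws of (beta, sigma) by simulating from the fitted model.

    Returns an array (n_boot, k + 1); the last column is sigma. A replicate
    whose refit fails is redrawn up to ``max_retries`` times, then recorded
    as NaN.
    """
    Zmat, names = _as_matrix(Z)
    mu = Zmat @ fit.beta
    k = Zmat.shape[1]
    out = np.full((n_boot, k + 1), np.nan)
    for b in range(n_boot):
        for _ in range(max_retries):
            dstar = sample_truncated(rng, mu, fit.sigma, fit.truncation)
            try:
                f = truncreg_mle(
                    dstar, Zmat, truncation=fit.truncation, names=names
                )
            except (InsufficientDataError, NumericalError):
                continue
            out[b, :k] = f.beta
            out[b, k] = f.sigma
            break
    return out
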