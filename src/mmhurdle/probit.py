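"""Two-level random-intercept probit for hospitalisation status.

The zero part of the hurdle: a binary probit with a Gaussian random
intercept for the individual's municipality of residence. The marginal
likelihood integrates the intercept per cluster with adaptive (mode-centred,
curvature-scaled) Gauss–Hermite quadrature; a plain (prior-centred)
quadrature is available as a cross-check. The variance is optimised on the
log scale so nonnegativity is automatic; estimates under ~1e-8 are reported
as boundary solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp, ndtr

__all__ = ["ProbitFit", "fit_probit", "probit_loglik", "predict_probability"]

_BOUNDARY_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries the best state seen so far."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best


class SeparationError(RuntimeError):
    """Complete separation: a coefficient is unbounded."""


@dataclass
class ProbitFit:
    """MLEs of the municipality-clustered probit."""

    alpha: pd.Series  # fixed effects, index = ['const', covariates...]
    sigma2_eps: float
    loglik: float
    n_obs: int
    n_groups: int
    n_quadrature_points: int
    direction: str  # 'hospitalised' (P(y>0)) or 'zero' (P(y=0))
    n_iter: int
    grad_norm: float
    boundary: bool
    converged: bool


def _mills(t: np.ndarray) -> np.ndarray:
    # phi(t)/Phi(t), computed stably via log densities
    return np.exp(-0.5 * t * t - 0.5 * np.log(2 * np.pi) - log_ndtr(t))


def _cluster_modes(
    eta: np.ndarray,
    q: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    sigma2: float,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster posterior mode and curvature of the integrand, by damped
    Newton on the scalar cluster effect (vectorised over clusters)."""
    b = np.zeros(n_groups)
    for _ in range(max_iter):
        t = q * (eta + b[group_idx])
        lam = _mills(t)
        g = np.bincount(group_idx, weights=q * lam, minlength=n_groups) - b / sigma2
        h = (
            -np.bincount(group_idx, weights=lam * (t + lam), minlength=n_groups)
            - 1.0 / sigma2
        )
        step = -g / h
        # dampen huge steps early on
        step = np.clip(step, -5.0, 5.0)
        b += step
        if np.max(np.abs(step)) < 1e-12:
            break
    t = q * (eta + b[group_idx])
    lam = _mills(t)
    h = (
        -np.bincount(group_idx, weights=lam * (t + lam), minlength=n_groups)
        - 1.0 / sigma2
    )
    return b, -h  # curvature (positive)


def probit_loglik(
    alpha: np.ndarray,
    sigma2: float,
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_quad: int = 15,
    adaptive: bool = True,
) -> float:
    """Marginal log-likelihood of the two-level probit at given parameters.

    ``y`` is the 0/1 response; ``group_idx`` maps rows to clusters.
    """
    n_groups = int(group_idx.max()) + 1 if len(group_idx) else 0
    eta = X @ alpha
    q = 2.0 * y - 1.0
    nodes, weights = hermgauss(n_quad)
    if sigma2 < 1e-12:
        return float(log_ndtr(q * eta).sum())

    def joint(b_vals: np.ndarray) -> np.ndarray:
        # log integrand per cluster at cluster-specific points b_vals[g]
        t = q * (eta + b_vals[group_idx])
        per = np.bincount(group_idx, weights=log_ndtr(t), minlength=n_groups)
        prior = -0.5 * b_vals**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        return per + prior

    if adaptive:
        b0, curv = _cluster_modes(eta, q, group_idx, n_groups, sigma2)
        tau = 1.0 / np.sqrt(curv)
        logs = np.empty((n_quad, n_groups))
        for m, (x, wt) in enumerate(zip(nodes, weights)):
            b_m = b0 + np.sqrt(2.0) * tau * x
            logs[m] = np.log(wt) + x * x + joint(b_m)
        ll = logsumexp(logs, axis=0) + 0.5 * np.log(2.0) + np.log(tau)
    else:
        s = np.sqrt(2.0 * sigma2)
        logs = np.empty((n_quad, n_groups))
        for m, (x, wt) in enumerate(zip(nodes, weights)):
            b_m = np.full(n_groups, s * x)
            t = q * (eta + b_m[group_idx])
            per = np.bincount(group_idx, weights=log_ndtr(t), minlength=n_groups)
            logs[m] = np.log(wt) + per
        ll = logsumexp(logs, axis=0) - 0.5 * np.log(np.pi)
    return float(ll.sum())


def _design(
    individuals: pd.DataFrame,
    covariates: list[str],
    direction: str,
    response_col: str,
    group_col: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    if direction not in ("hospitalised", "zero"):
        raise ValueError("direction must be 'hospitalised' or 'zero'")
    missing = [c for c in covariates if c not in individuals.columns]
    if missing:
        raise ValueError(f"covariates not in table: {missing}")
    X = np.column_stack(
        [np.ones(len(individuals))]
        + [individuals[c].to_numpy(dtype=float) for c in covariates]
    )
    raw = individuals[response_col].to_numpy()
    y = (raw > 0).astype(float) if response_col == "n_hospitalisations" else raw.astype(float)
    if direction == "zero":
        y = 1.0 - y
    groups, group_idx = np.unique(individuals[group_col], return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least two municipalities")
    return X, y, group_idx, ["const"] + list(covariates), len(groups)


def fit_probit(
    individuals: pd.DataFrame,
    covariates: list[str] | None = None,
    direction: str = "hospitalised",
    response_col: str = "n_hospitalisations",
    group_col: str = "residence_municipality_id",
    n_quad: int = 15,
    adaptive: bool = True,
    max_iter: int = 200,
) -> ProbitFit:
    """Maximum-likelihood fit of the municipality-clustered probit.

    ``direction="hospitalised"`` models P(y > 0) (the reported convention);
    ``"zero"`` models P(y = 0). The two differ only by the sign of the fixed
    effects — the variance and log-likelihood are identical.
    """
    covariates = list(covariates or [])
    X, y, group_idx, names, n_groups = _design(
        individuals, covariates, direction, response_col, group_col
    )
    if y.min() == y.max():
        raise SeparationError("response is constant; coefficients unbounded")

    # starting values: single-level probit MLE, small cluster variance
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_alpha = sm.Probit(y, X).fit(disp=0, maxiter=200).params
        if not np.all(np.isfinite(start_alpha)):
            raise ValueError
    except Exception:
        start_alpha = np.zeros(X.shape[1])  # separation handled post-fit
    theta0 = np.append(start_alpha, np.log(0.05))

    def nll(theta: np.ndarray) -> float:
        return -probit_loglik(
            theta[:-1], np.exp(theta[-1]), X, y, group_idx, n_quad, adaptive
        )

    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-30.0, 5.0)],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    alpha = res.x[:-1]
    sigma2 = float(np.exp(res.x[-1]))
    scale = np.abs(X).mean(axis=0)
    if np.any(np.abs(alpha) * np.maximum(scale, 1e-12) > 50):
        raise SeparationError(
            "fitted coefficients diverge; data are likely completely separated"
        )
    if not res.success and grad_norm > 1e-2:
        raise ConvergenceError(
            f"probit did not converge: {res.message}",
            best={"alpha": alpha, "sigma2_eps": sigma2, "loglik": -res.fun},
        )
    return ProbitFit(
        alpha=pd.Series(alpha, index=names),
        sigma2_eps=sigma2,
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        n_quadrature_points=n_quad,
        direction=direction,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        boundary=sigma2 < _BOUNDARY_TOL,
        converged=bool(res.success),
    )


def predict_probability(
    fit: ProbitFit, newdata: pd.DataFrame, kind: str = "population"
) -> np.ndarray:
    """Predicted event probability for new individuals.

    ``kind="population"`` averages over the municipality effect,
    Phi(x'a / sqrt(1 + sigma2)); ``"conditional"`` sets the effect to zero,
    Phi(x'a).
    """
    covariates = [c for c in fit.alpha.index if c != "const"]
    missing = [c for c in covariates if c not in newdata.columns]
    if missing:
        raise ValueError(f"newdata missing covariates: {missing}")
    X = np.column_stack(
        [np.ones(len(newdata))]
        + [newdata[c].to_numpy(dtype=float) for c in covariates]
    )
    eta = X @ fit.alpha.to_numpy()
    if kind == "population":
        return ndtr(eta / np.sqrt(1.0 + fit.sigma2_eps))
    if kind == "conditional":
        return ndtr(eta)
    raise ValueError("kind must be 'population' or 'conditional'")
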