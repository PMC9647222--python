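"""Minimal logistic-regression core shared by selection and modelling.

Maximum-likelihood fit by iteratively reweighted least squares (IRLS).
Convergence: relative log-likelihood change below 1e-8 or 100 iterations.
Perfect separation (diverging coefficients) is detected and the fit is
stabilised with a weak L2 penalty (lambda = 1e-6) plus a warning, so the
search procedures that call this never abort on separable subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import InvalidInputError

_MAX_ITER = 100
_TOL = 1e-8
_SEPARATION_BOUND = 30.0
_STABILISING_RIDGE = 1e-6


@dataclass
class LogisticFit:
    """Fitted coefficients: ``beta[0]`` is the intercept."""

    beta: np.ndarray
    deviance: float
    converged: bool
    separation: bool
    n_obs: int

    @property
    def n_params(self) -> int:
        return self.beta.size

    def bic(self) -> float:
        return self.deviance + self.n_params * np.log(self.n_obs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xd = _design(np.asarray(X, dtype=float))
        return special.expit(Xd @ self.beta)


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log sigma(eta) = -log1p(exp(-eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(Xd: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, bool]:
    n, k = Xd.shape
    beta = np.zeros(k)
    p0 = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[0] = special.logit(p0)
    ll_old = _loglik(y, Xd @ beta)
    converged = False
    pen = ridge * np.eye(k)
    pen[0, 0] = 0.0  # never penalise the intercept
    for _ in range(_MAX_ITER):
        eta = Xd @ beta
        p = special.expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        xtw = Xd.T * w
        try:
            beta_new = np.linalg.solve(xtw @ Xd + pen, xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtw @ Xd + pen, xtw @ z, rcond=None)[0]
        ll_new = _loglik(y, Xd @ beta_new)
        # step-halve if the update worsens the penalised likelihood
        step = 1.0
        while ll_new < ll_old - 1e-12 and step > 1e-4:
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            ll_new = _loglik(y, Xd @ beta_new)
        beta = beta_new
        if abs(ll_new - ll_old) <= _TOL * (abs(ll_old) + _TOL):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    return beta, converged


def fit_logistic_core(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Fit logit P(y=1) = b0 + X beta by maximum likelihood.

    ``X`` has shape (n, k); k = 0 fits an intercept-only model.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((y.size, 0))
    if y.size != X.shape[0]:
        raise InvalidInputError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("outcome has a single class")
    Xd = np.column_stack([np.ones(y.size), X])
    beta, converged = _irls(Xd, y, ridge=0.0)
    # diverging coefficients, or a perfect (zero-deviance) fit reached on
    # the way to divergence, both signal separation
    dev0 = -2.0 * _loglik(y, Xd @ beta)
    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND or
                      (X.shape[1] > 0 and dev0 < 1e-6 * y.size))
    if separation:
        warnings.warn(
            "perfect separation detected; refitting with weak L2 penalty",
            stacklevel=2,
        )
        beta, converged = _irls(Xd, y, ridge=_STABILISING_RIDGE)
    eta = Xd @ beta
    deviance = -2.0 * _loglik(y, eta)
    return LogisticFit(beta=beta, deviance=deviance, converged=converged,
                       separation=separation, n_obs=y.size)
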