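"""Weighted multinomial logistic regression.

Maximises the weighted multinomial log-likelihood

    l(B) = sum_n w_n log p_{n, y_n},   p_{nj} = softmax_j(x_n' b_j)

with one outcome (the pivot) fixed at b = 0. Weights are treated as
probability weights: point estimates are invariant to rescaling the
weights; the reported covariance is the inverse observed information of the
weighted likelihood.

Newton-Raphson with analytic gradient and Hessian and step-halving; falls
back to L-BFGS and, under (quasi-)separation, to a small ridge penalty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FittingError

logger = logging.getLogger(__name__)

__all__ = ["MNLogitFit", "fit_weighted_mnlogit", "mnlogit_proba"]


@dataclass
class MNLogitFit:
    """Fitted weighted multinomial logit.

    ``coef`` has shape (P, K) with the pivot column identically zero.
    ``cov`` is the covariance of the free parameters, flattened
    column-major over non-pivot outcomes (order: outcome, then covariate).
    """

    coef: np.ndarray
    pivot: int
    classes: np.ndarray
    loglik: float
    deviance: float
    cov: np.ndarray | None
    converged: bool
    n_iter: int
    ridge: float = 0.0


def mnlogit_proba(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a (P, K) coefficient matrix."""
    eta = X @ coef
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _loglik_grad_hess(B_free, X, Yonehot, w, free, need_hess=True):
    n, P = X.shape
    K = Yonehot.shape[1]
    coef = np.zeros((P, K))
    coef[:, free] = B_free
    p = mnlogit_proba(coef, X)
    ll = float(np.sum(w * np.log(np.maximum(p[Yonehot.astype(bool)], 1e-300))))
    resid = (Yonehot - p)[:, free] * w[:, None]          # (n, Kf)
    grad = X.T @ resid                                   # (P, Kf)
    if not need_hess:
        return ll, grad, None
    Kf = len(free)
    H = np.empty((P * Kf, P * Kf))
    pw = p[:, free] * w[:, None]
    for a in range(Kf):
        for b in range(a, Kf):
            if a == b:
                d = pw[:, a] * (1.0 - p[:, free[a]])
            else:
                d = -pw[:, a] * p[:, free[b]]
            block = X.T @ (X * d[:, None])
            H[a * P:(a + 1) * P, b * P:(b + 1) * P] = block
            H[b * P:(b + 1) * P, a * P:(a + 1) * P] = block.T
    return ll, grad, H


def fit_weighted_mnlogit(X: np.ndarray, y: np.ndarray, w: np.ndarray | None,
                         n_classes: int | None = None, pivot: int = 0,
                         tol: float = 1e-8, max_iter: int = 200,
                         ridge: float = 0.0) -> MNLogitFit:
    """Fit a weighted multinomial logit with outcome ``pivot`` as reference.

    ``y`` holds integer class codes 0..K-1. Convergence is declared when
    the weight-normalised gradient max-norm drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, P = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise FittingError("weights must be strictly positive")
    K = int(n_classes if n_classes is not None else y.max() + 1)
    classes = np.arange(K)
    free = [k for k in range(K) if k != pivot]
    Yonehot = np.zeros((n, K))
    Yonehot[np.arange(n), y] = 1.0
    wsum = w.sum()

    def newton(lam):
        B = np.zeros((P, len(free)))
        ll, grad, H = _loglik_grad_hess(B, X, Yonehot, w, free)
        ll -= 0.5 * lam * np.sum(B * B)
        for it in range(1, max_iter + 1):
            g = grad.flatten(order="F") - lam * B.flatten(order="F")
            if np.max(np.abs(g)) / wsum < tol:
                return B, ll, it, True
            Hp = H + lam * np.eye(H.shape[0])
            try:
                step = np.linalg.solve(Hp, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hp, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                Bn = B + t * step.reshape(B.shape, order="F")
                lln, gradn, Hn = _loglik_grad_hess(Bn, X, Yonehot, w, free)
                lln -= 0.5 * lam * np.sum(Bn * Bn)
                if lln >= ll - 1e-12:
                    break
                t *= 0.5
            else:
                return B, ll, it, False
            B, ll, grad, H = Bn, lln, gradn, Hn
        return B, ll, max_iter, False

    lam = ridge
    B, ll, n_iter, ok = newton(lam)
    if not ok or not np.all(np.isfinite(B)):
        if lam == 0.0:
            logger.warning("possible separation in multinomial logit; "
                           "refitting with ridge 1e-6 * sum(w)")
            lam = 1e-6 * wsum
            B, ll, n_iter, ok = newton(lam)
        if not ok:
            # last resort: L-BFGS on the penalised likelihood
            from scipy.optimize import minimize

            def negll(flat):
                Bm = flat.reshape((P, len(free)), order="F")
                l_, g_, _ = _loglik_grad_hess(Bm, X, Yonehot, w, free,
                                              need_hess=False)
                l_ -= 0.5 * lam * np.sum(Bm * Bm)
                g = g_.flatten(order="F") - lam * flat
                return -l_, -g

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(negll, B.flatten(order="F"), jac=True,
                               method="L-BFGS-B",
                               options={"maxiter": 2000, "ftol": 1e-14,
                                        "gtol": tol * wsum})
            B = res.x.reshape((P, len(free)), order="F")
            ll, _, _ = _loglik_grad_hess(B, X, Yonehot, w, free,
                                         need_hess=False)
            ok = res.success

    coef = np.zeros((P, K))
    coef[:, free] = B
    ll_final, _, H = _loglik_grad_hess(B, X, Yonehot, w, free)
    cov = None
    try:
        cov = np.linalg.inv(H + lam * np.eye(H.shape[0]))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate designs
        pass
    return MNLogitFit(coef=coef, pivot=pivot, classes=classes,
                      loglik=ll_final, deviance=-2.0 * ll_final, cov=cov,
                      converged=ok, n_iter=n_iter, ridge=lam)
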