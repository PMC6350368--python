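"""Maximum-likelihood binary logistic regression.

The model is the standard logit link,

    P(y = 1 | x) = exp(w.x) / (1 + exp(w.x)),

fit by maximizing the log-likelihood

    L(w) = sum_i [ y_i (w.x_i) - log(1 + exp(w.x_i)) ]

with Newton-Raphson and step-halving.  The objective is concave, the design
has only three columns (constant, phi1, phi0), and the exact Hessian is
cheap, so Newton converges in a handful of steps.  A tiny ridge penalty
(default 1e-8, settable to 0) keeps the fit finite under complete
separation, which small per-disease label vectors can produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

DEFAULT_TOL = 1e-8
DEFAULT_RIDGE = 1e-8
DEFAULT_MAX_ITER = 100


@dataclass
class RegressionModel:
    w: np.ndarray
    loglik: float
    grad_norm: float
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "w": [float(v) for v in self.w],
                "loglik": self.loglik,
                "grad_norm": self.grad_norm,
                "iterations": self.iterations,
                "converged": self.converged,
            },
            indent=2,
        )


def log_likelihood(w: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """L(w) = sum_i [y_i z_i - log(1 + exp(z_i))], overflow-safe via logaddexp."""
    z = np.asarray(X, float) @ np.asarray(w, float)
    return float(np.sum(np.asarray(y, float) * z - np.logaddexp(0.0, z)))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = DEFAULT_TOL,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RegressionModel:
    """Newton-Raphson MLE with step-halving.

    Convergence is declared on the infinity norm of the (penalized) score
    vector X'(y - pi) - ridge * w.  Requires at least one positive and one
    negative label; a disease with no known associated miRNA has nothing to
    learn from.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching numbers of rows")
    if y.sum() == 0:
        raise ValueError("disease has no known associations; model cannot be trained")
    if y.sum() == y.shape[0]:
        raise ValueError("all labels positive; model cannot be trained")

    p = X.shape[1]
    w = np.zeros(p)

    def penalized(wv: np.ndarray) -> float:
        return log_likelihood(wv, X, y) - 0.5 * ridge * float(wv @ wv)

    ll = penalized(w)
    trace = [ll]
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        pi = expit(X @ w)
        grad = X.T @ (y - pi) - ridge * w
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol:
            return RegressionModel(w, log_likelihood(w, X, y), grad_norm, it - 1, True, trace)
        wgt = pi * (1.0 - pi)
        H = -(X.T * wgt) @ X - ridge * np.eye(p)
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, grad, rcond=None)[0]
        # step-halving: accept the first step that does not decrease the objective
        scale = 1.0
        for _ in range(30):
            w_new = w + scale * step
            ll_new = penalized(w_new)
            if ll_new >= ll - 1e-13:
                break
            scale /= 2.0
        w, ll = w_new, ll_new
        trace.append(ll)

    pi = expit(X @ w)
    grad = X.T @ (y - pi) - ridge * w
    grad_norm = float(np.abs(grad).max())
    return RegressionModel(
        w, log_likelihood(w, X, y), grad_norm, max_iter, grad_norm < tol, trace
    )


def predict(model: RegressionModel, X: np.ndarray) -> np.ndarray:
    """Posterior association probabilities P(y=1|x) per row of X."""
    return expit(np.asarray(X, float) @ model.w)
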