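"""Minimal logistic-regression core (Newton/IRLS).

The psychometric analyses refit the same tiny logistic model tens of
thousands of times (case-resample bootstrap, coverage sweeps), so the fit is
implemented directly on top of numpy; it is cross-checked against statsmodels
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logit_irls", "sigmoid"]


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function 1/(1+exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    Parameters
    ----------
    X : (n, p) design matrix (include the constant column yourself).
    y : (n,) binary responses in {0, 1}.
    ridge : small L2 penalty added to the Hessian only as a numerical
        safeguard; 0 keeps the plain MLE.

    Returns
    -------
    beta : (p,) coefficient vector.
    cov : (p, p) inverse observed information (asymptotic covariance).
    converged : False when Newton did not reach ``tol`` (e.g. quasi-complete
        separation drives coefficients to infinity).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        if ridge:
            H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (separation): keeps iteration finite
        norm = np.max(np.abs(step))
        if norm > 50.0:
            step *= 50.0 / norm
        beta = beta + step
        if norm < tol:
            converged = True
            break
    eta = X @ beta
    mu = sigmoid(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged
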