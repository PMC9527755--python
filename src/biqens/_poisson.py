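"""Poisson maximum-likelihood machinery shared by all spectral fits.

The objective everywhere is the Poisson deviance
D = 2 Σ [m − n + n·ln(n/m)] (= −2 log L up to a data-only constant), reported
as χ²_ν = D / (n_data − n_free).  Minimization uses L-BFGS-B with analytic
gradients supplied by the model evaluators; uncertainties come from the
observed information (finite-difference Hessian of the deviance built from
the analytic gradient).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["poisson_deviance", "deviance_residual_factor", "minimize_deviance",
           "deviance_hessian", "covariance_from_hessian"]

_FLOOR = 1e-12


def poisson_deviance(counts: np.ndarray, model: np.ndarray) -> float:
    """Poisson deviance; counts may contain zeros, model must be >= 0."""
    m = np.maximum(model, _FLOOR)
    n = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        nlog = np.where(n > 0, n * np.log(np.where(n > 0, n, 1.0) / m), 0.0)
    return float(2.0 * np.sum(m - n + nlog))


def deviance_residual_factor(counts: np.ndarray, model: np.ndarray) -> np.ndarray:
    """∂D/∂m = 2·(1 − n/m); contract with ∂m/∂θ to get the gradient."""
    m = np.maximum(model, _FLOOR)
    return 2.0 * (1.0 - counts / m)


def minimize_deviance(fun_and_grad, x0, bounds, maxiter=600, ftol=1e-10):
    """L-BFGS-B on a callable returning (deviance, gradient).

    Returns the scipy result augmented with a monotone objective trace
    (best-so-far at each accepted iteration).
    """
    trace: list[float] = []
    last = [np.inf]

    def fun(x):
        f, g = fun_and_grad(x)
        last[0] = f
        return f, g

    def cb(xk):
        trace.append(last[0] if not trace else min(trace[-1], last[0]))

    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   callback=cb, options={"maxiter": maxiter, "ftol": ftol,
                                         "maxcor": 20})
    res.trace = np.asarray(trace)
    return res


def deviance_hessian(fun_and_grad, x, step=1e-5):
    """Central-difference Hessian of the deviance from analytic gradients."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    for i in range(p):
        h = step * max(abs(x[i]), 1e-3)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fun_and_grad(xp)
        _, gm = fun_and_grad(xm)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def covariance_from_hessian(H, x=None, bounds=None, grad=None, tol=1e-7):
    """Parameter covariance = 2·H⁻¹ for a deviance Hessian H.

    Parameters pinned at an active box bound (with the gradient pushing
    outward) are treated as fixed: their rows/columns are dropped before
    inversion and restored as zero variance.
    """
    p = H.shape[0]
    free = np.ones(p, dtype=bool)
    if x is not None and bounds is not None:
        for i, (lo, hi) in enumerate(bounds):
            scale = max(abs(x[i]), 1.0)
            at_lo = lo is not None and abs(x[i] - lo) < tol * scale
            at_hi = hi is not None and abs(x[i] - hi) < tol * scale
            if at_lo or at_hi:
                if grad is None:
                    free[i] = False
                elif (at_lo and grad[i] > 0) or (at_hi and grad[i] < 0):
                    free[i] = False
    Hf = H[np.ix_(free, free)]
    try:
        cov_f = 2.0 * np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        cov_f = 2.0 * np.linalg.pinv(Hf)
    if np.any(np.diag(cov_f) < 0):
        cov_f = 2.0 * np.linalg.pinv(Hf, rcond=1e-10)
    cov = np.zeros((p, p))
    cov[np.ix_(free, free)] = cov_f
    return cov
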