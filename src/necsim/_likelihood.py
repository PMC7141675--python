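"""Binomial likelihood helpers shared by the fitters."""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_P_EPS = 1e-12


def binom_loglik_const(y: np.ndarray, n: np.ndarray) -> float:
    """The parameter-free log binomial coefficient term."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    return float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))


def binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray, const: float = 0.0) -> float:
    """Binomial log-likelihood with probabilities clipped away from {0, 1}
    for numerical stability."""
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p))) + const


def numeric_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function; steps are relative
    to parameter magnitude with an absolute floor."""
    x0 = np.asarray(x0, float)
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-6)
    hess = np.empty((k, k))
    f0 = fun(x0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp = x0.copy(); xp[i] += h[i]
                xm = x0.copy(); xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess


def covariance_from_hessian(hess: np.ndarray):
    """Invert an observed-information matrix, returning ``(cov, ok)``.

    ``ok`` is False when the Hessian is singular or not positive definite,
    in which case a Moore-Penrose pseudo-inverse is returned and callers
    should flag the fit rather than trust the standard errors.
    """
    if not np.all(np.isfinite(hess)):
        k = hess.shape[0]
        return np.full((k, k), np.nan), False
    try:
        eigvals = np.linalg.eigvalsh(hess)
        if np.all(eigvals > 0) and eigvals.min() > 1e-10 * max(eigvals.max(), 1.0):
            return np.linalg.inv(hess), True
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(hess), False
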