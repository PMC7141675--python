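"""Maximum-likelihood fitting of the threshold (NEC) survival model.

The binomial log-likelihood is smooth in the intercept and decay rate but
only piecewise-smooth in the threshold (kinks at every observed
concentration), so a plain quasi-Newton search is unreliable. The fitter
profiles the threshold instead: a coarse candidate grid (observed
concentrations plus midpoints) with an inner smooth 2-parameter
optimization at each candidate, followed by bounded scalar refinement of
the threshold around the best candidate. This finds the global optimum up
to the refinement tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from ._likelihood import (
    binom_loglik,
    binom_loglik_const,
    covariance_from_hessian,
    numeric_hessian,
)
from .result import FitResult
from .simulate import SurvivalDataset

__all__ = ["fit_nec_mle", "profile_threshold_grid", "nec_ecx_from_fit"]

_Z95 = 1.959963984540054


def _nec_prob(x, l, m, c):
    return l * np.exp(-m * np.maximum(x - c, 0.0))


def _inner_nll_factory(x, y, n, const):
    def make(c):
        z = np.maximum(x - c, 0.0)

        def nll_and_grad(theta):
            l = expit(theta[0])
            m = np.exp(theta[1])
            p = l * np.exp(-m * z)
            pc = np.clip(p, 1e-12, 1.0 - 1e-12)
            f = -(np.sum(y * np.log(pc) + (n - y) * np.log1p(-pc)) + const)
            s = y / pc - (n - y) / (1.0 - pc)
            g0 = -np.sum(s * p * (1.0 - l))
            g1 = -np.sum(s * (-z * m * p))
            return f, np.array([g0, g1])

        return nll_and_grad

    return make


def _profile(x, y, n, const, c, start):
    """Maximize over (l, m) at fixed threshold; returns (nll, theta_hat)."""
    make = _inner_nll_factory(x, y, n, const)
    res = minimize(
        make(c), start, method="L-BFGS-B", jac=True,
        bounds=[(-10.0, 10.0), (np.log(1e-3), np.log(1e4))],
        options={"ftol": 1e-13, "gtol": 1e-9},
    )
    return res.fun, res.x


def _profile_multi(x, y, n, const, c, warm):
    """Inner optimization from the warm start plus fixed shallow/steep
    starts; the inner surface can be multimodal in the decay rate."""
    l0 = _start_theta(x, y, n)[0]
    best = _profile(x, y, n, const, c, warm)
    for m0 in (2.0, 12.0):
        cand = _profile(x, y, n, const, c, np.array([l0, np.log(m0)]))
        if cand[0] < best[0]:
            best = cand
    return best


def _start_theta(x, y, n):
    ctrl = x == 0
    l0 = y[ctrl].sum() / n[ctrl].sum() if ctrl.any() else y.max() / n.max()
    l0 = float(np.clip(l0, 0.05, 0.995))
    return np.array([logit(l0), np.log(5.0)])


def fit_nec_mle(
    dataset: SurvivalDataset, ecx_levels=(0.05, 0.10, 0.50), refine_tol: float = 1e-6
) -> FitResult:
    """Fit the threshold model by profile MLE with delta-method CI for the
    threshold.

    The threshold is constrained to ``[0, max(x))``. When the observed
    information at the optimum is indefinite (kinks can corrupt curvature),
    the fit is flagged via ``extras['hessian_indefinite']`` rather than
    excluded, and standard errors fall back to a pseudo-inverse.
    """
    x = dataset.concentration
    y = dataset.n_survived.astype(float)
    n = dataset.n_exposed.astype(float)
    const = binom_loglik_const(y, n)

    # The profile is smooth in c within each interval between consecutive
    # observed concentrations (the set of units beyond the threshold is
    # fixed there), so scan every interval coarsely and refine the most
    # promising ones with bounded scalar minimization.
    edges = np.unique(np.concatenate([[0.0], np.unique(x)]))
    intervals = list(zip(edges[:-1], edges[1:]))
    warm_cell = [_start_theta(x, y, n)]

    def prof_nll(c):
        val, th = _profile(x, y, n, const, float(c), warm_cell[0])
        warm_cell[0] = th
        return val

    coarse_val = []
    for a, b in intervals:
        coarse_val.append(min(prof_nll(p) for p in np.linspace(a, b, 4)))
    order = np.argsort(coarse_val)[:3]

    # dense multi-start scan of the top intervals, then Brent refinement
    # bracketed around the best scan point (the profile can be multimodal
    # in the threshold even inside one interval)
    c_hat, best_nll = None, np.inf
    for i in order:
        a, b = intervals[i]
        pts = np.linspace(a, b, 9)
        vals = []
        for p in pts:
            v, th = _profile_multi(x, y, n, const, float(p), warm_cell[0])
            warm_cell[0] = th
            vals.append(v)
        j = int(np.argmin(vals))
        lo_j = pts[max(j - 1, 0)]
        hi_j = pts[min(j + 1, len(pts) - 1)]
        res = minimize_scalar(
            prof_nll, bounds=(lo_j, hi_j), method="bounded",
            options={"xatol": refine_tol},
        )
        for c_cand, v_cand in (
            (float(res.x), float(res.fun)),
            (float(pts[j]), vals[j]),
        ):
            if v_cand < best_nll:
                c_hat, best_nll = c_cand, v_cand
    best_nll, theta_hat = _profile_multi(x, y, n, const, c_hat, warm_cell[0])

    l_hat = float(expit(theta_hat[0]))
    m_hat = float(np.exp(theta_hat[1]))

    fit = FitResult(
        model_tag="nec_mle",
        estimates={"l": l_hat, "m": m_hat, "c": c_hat},
        loglik=-float(best_nll),
        n_params=3,
        converged=True,
    )

    def nll_natural(theta):
        l, m, c = theta
        if not (0 < l <= 1 and m > 0):
            return np.inf
        return -binom_loglik(y, n, _nec_prob(x, l, m, np.maximum(c, 0.0)), const)

    hess = numeric_hessian(nll_natural, np.array([l_hat, m_hat, c_hat]))
    cov, cov_ok = covariance_from_hessian(hess)
    fit.extras["covariance"] = cov
    fit.extras["covariance_ok"] = cov_ok
    fit.extras["hessian_indefinite"] = not cov_ok
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    fit.standard_errors = {"l": float(se[0]), "m": float(se[1]), "c": float(se[2])}

    if cov_ok:
        se_c = fit.standard_errors["c"]
        fit.extras["threshold_ci"] = (c_hat - _Z95 * se_c, c_hat + _Z95 * se_c)
        fit.apply_wide_ci_rule([fit.extras["threshold_ci"]])
    else:
        fit.extras["threshold_ci"] = (float("nan"), float("nan"))

    for q in ecx_levels:
        fit.ecx_estimates[q] = nec_ecx_from_fit(fit, q)
    return fit


def nec_ecx_from_fit(fit: FitResult, q: float):
    """ECx implied by a fitted threshold model, ``c + ln(1/(1-q))/m``, with
    a delta-method 95% CI. Always at or above the fitted threshold."""
    m = fit.estimates["m"]
    c = fit.estimates["c"]
    shift = -np.log1p(-q)
    point = c + shift / m
    cov = fit.extras.get("covariance")
    if cov is None or not fit.extras.get("covariance_ok", False):
        return (float(point), float("nan"), float("nan"))
    grad = np.array([0.0, -shift / m**2, 1.0])
    var = float(grad @ cov @ grad)
    se = np.sqrt(var) if var > 0 else float("nan")
    return (float(point), float(point - _Z95 * se), float(point + _Z95 * se))


def profile_threshold_grid(dataset: SurvivalDataset, grid: np.ndarray):
    """Profile log-likelihood over an explicit threshold grid (the oracle
    used to verify global optimality of :func:`fit_nec_mle`). Returns
    ``(grid, loglik_values)``."""
    x = dataset.concentration
    y = dataset.n_survived.astype(float)
    n = dataset.n_exposed.astype(float)
    const = binom_loglik_const(y, n)
    theta = _start_theta(x, y, n)
    out = np.empty(len(grid))
    for i, c in enumerate(grid):
        nll, theta = _profile_multi(x, y, n, const, float(c), theta)
        out[i] = -nll
    return np.asarray(grid, float), out
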