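"""Maximum-likelihood fitting of the three-parameter log-logistic curve
with delta-method ECx confidence intervals.

The binomial log-likelihood is maximized by bounded quasi-Newton (L-BFGS-B)
on a transformed parameter scale (logit for the asymptote, log for slope and
inflection), with a small multi-start around a data-driven heuristic to
guard against local optima. Standard errors come from the inverse observed
information on the natural ``(d, b, e)`` scale.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._likelihood import (
    binom_loglik,
    binom_loglik_const,
    covariance_from_hessian,
    numeric_hessian,
)
from .curves import LogLogisticParams, loglogistic_survival_prob
from .result import FitResult
from .simulate import SurvivalDataset

__all__ = ["fit_loglogistic3", "estimate_ecx"]

_Z95 = 1.959963984540054
DEFAULT_ECX_LEVELS = (0.05, 0.10, 0.50)


def _ll3_prob(x: np.ndarray, d: float, b: float, e: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        ratio = np.where(x > 0, x / e, 1.0)
        return np.where(x > 0, d / (1.0 + ratio**b), d)


def _make_nll(x, y, n, const):
    def nll(theta):
        d = expit(theta[0])
        b = np.exp(theta[1])
        e = np.exp(theta[2])
        return -binom_loglik(y, n, _ll3_prob(x, d, b, e), const)

    return nll


def _starts(x, y, n):
    """Heuristic start plus perturbations: d from the control mean, e from
    the concentration nearest 50% relative kill, b around 5."""
    ctrl = x == 0
    if ctrl.any():
        d0 = y[ctrl].sum() / n[ctrl].sum()
    else:
        d0 = y.max() / n[np.argmax(y)]
    d0 = float(np.clip(d0, 0.05, 0.995))
    pos = x > 0
    frac = y / n
    if pos.any():
        target = d0 / 2.0
        e0 = float(x[pos][np.argmin(np.abs(frac[pos] - target))])
        e0 = max(e0, 1e-3)
    else:
        e0 = 0.3
    for b0, e_scale in ((5.0, 1.0), (2.0, 1.5), (10.0, 0.75)):
        yield np.array([logit(d0), np.log(b0), np.log(e0 * e_scale)])


def fit_loglogistic3(
    dataset: SurvivalDataset, ecx_levels=DEFAULT_ECX_LEVELS
) -> FitResult:
    """Fit the three-parameter log-logistic model by MLE and attach
    delta-method ECx estimates for the requested effect levels.

    Non-convergence or any ECx interval wider than 100 percentage points
    marks the result excluded.
    """
    x = dataset.concentration
    y = dataset.n_survived.astype(float)
    n = dataset.n_exposed.astype(float)
    const = binom_loglik_const(y, n)
    nll = _make_nll(x, y, n, const)

    best = None
    for start in _starts(x, y, n):
        res = minimize(nll, start, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res

    d = float(expit(best.x[0]))
    b = float(np.exp(best.x[1]))
    e = float(np.exp(best.x[2]))

    fit = FitResult(
        model_tag="loglogistic3_mle",
        estimates={"d": d, "b": b, "e": e},
        loglik=-float(best.fun),
        n_params=3,
    )

    # Degenerate optima (runaway slope/inflection) carry no dose-response
    # information even when the optimizer reports success.
    degenerate = not best.success or b > 1e3 or e > 1e3 or e < 1e-6
    if degenerate:
        fit.converged = False
        return fit.exclude("nonconvergence")
    fit.converged = True

    def nll_natural(theta):
        return -binom_loglik(y, n, _ll3_prob(x, *theta), const)

    hess = numeric_hessian(nll_natural, np.array([d, b, e]))
    cov, cov_ok = covariance_from_hessian(hess)
    fit.extras["covariance"] = cov
    fit.extras["covariance_ok"] = cov_ok
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    fit.standard_errors = {"d": float(se[0]), "b": float(se[1]), "e": float(se[2])}

    if not cov_ok:
        fit.exclude("singular_covariance")
        return fit

    for q in ecx_levels:
        fit.ecx_estimates[q] = estimate_ecx(fit, q)
    fit.apply_wide_ci_rule(
        (lo, hi) for (_pt, lo, hi) in fit.ecx_estimates.values()
    )
    return fit


def estimate_ecx(fit: FitResult, q: float):
    """Delta-method ECx point and 95% CI from a converged log-logistic fit.

    ECx = ``e * (q/(1-q))**(1/b)``; the gradient with respect to the
    asymptote is zero because the effect level is defined relative to the
    curve's own intercept.
    """
    if not fit.converged:
        raise ValueError("ECx requires a converged fit")
    b = fit.estimates["b"]
    e = fit.estimates["e"]
    odds = q / (1.0 - q)
    point = e * odds ** (1.0 / b)
    cov = fit.extras.get("covariance")
    if cov is None or not fit.extras.get("covariance_ok", False):
        return (float(point), float("nan"), float("nan"))
    grad = np.array([0.0, -point * np.log(odds) / b**2, odds ** (1.0 / b)])
    var = float(grad @ cov @ grad)
    se = np.sqrt(var) if var > 0 else float("nan")
    return (float(point), float(point - _Z95 * se), float(point + _Z95 * se))


def predicted_survival(fit: FitResult, x):
    params = LogLogisticParams(
        min(fit.estimates["d"], 1.0), fit.estimates["b"], fit.estimates["e"]
    )
    return loglogistic_survival_prob(params, x)
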