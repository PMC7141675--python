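"""Closed-form survival curves and their analytic ECx / threshold values.

Two curve families are supported:

* a threshold ("no-effect concentration", NEC) curve: survival equals the
  control level up to a threshold concentration and decays exponentially
  beyond it;
* a three-parameter log-logistic curve with an upper asymptote below 1 to
  encode background mortality.

Concentrations are fractions in ``[0, 1]`` internally; percent is a display
convention only (the decay/slope constants 3, 5, 10 only make sense on the
fraction scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterDomainError",
    "NECParams",
    "LogLogisticParams",
    "ECxQuery",
    "nec_survival_prob",
    "loglogistic_survival_prob",
    "analytic_ecx_nec",
    "analytic_ecx_loglogistic",
    "matched_loglogistic_from_nec",
]


class ParameterDomainError(ValueError):
    """Raised when curve parameters or queries fall outside their domain."""


@dataclass(frozen=True)
class NECParams:
    """Parameters of the threshold survival curve.

    Attributes
    ----------
    intercept_l:
        Survival probability at concentration 0, in ``(0, 1]``.
    slope_m:
        Exponential decay rate per unit concentration fraction, ``> 0``.
    threshold_c:
        Threshold concentration fraction in ``[0, 1)``; survival equals
        ``intercept_l`` for all concentrations at or below it.
    """

    intercept_l: float
    slope_m: float
    threshold_c: float

    def __post_init__(self) -> None:
        if not 0.0 < self.intercept_l <= 1.0:
            raise ParameterDomainError(
                f"intercept_l must be in (0, 1], got {self.intercept_l}"
            )
        if not self.slope_m > 0.0:
            raise ParameterDomainError(f"slope_m must be > 0, got {self.slope_m}")
        if not 0.0 <= self.threshold_c < 1.0:
            raise ParameterDomainError(
                f"threshold_c must be in [0, 1), got {self.threshold_c}"
            )


@dataclass(frozen=True)
class LogLogisticParams:
    """Parameters of the three-parameter log-logistic survival curve.

    Attributes
    ----------
    intercept_d:
        Upper asymptote (control survival), in ``(0, 1]``.
    slope_b:
        Unitless steepness, ``> 0``.
    inflection_e:
        Concentration fraction at which survival halves relative to the
        asymptote (the EC50), ``> 0``.
    """

    intercept_d: float
    slope_b: float
    inflection_e: float

    def __post_init__(self) -> None:
        if not 0.0 < self.intercept_d <= 1.0:
            raise ParameterDomainError(
                f"intercept_d must be in (0, 1], got {self.intercept_d}"
            )
        if not self.slope_b > 0.0:
            raise ParameterDomainError(f"slope_b must be > 0, got {self.slope_b}")
        if not self.inflection_e > 0.0:
            raise ParameterDomainError(
                f"inflection_e must be > 0, got {self.inflection_e}"
            )


@dataclass(frozen=True)
class ECxQuery:
    """An effective-concentration query: the concentration producing a
    fractional reduction ``effect_fraction_q`` in survival *relative to the
    curve's own intercept* (survival = ``(1 - q) * intercept``)."""

    effect_fraction_q: float

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_fraction_q < 1.0:
            raise ParameterDomainError(
                f"effect_fraction_q must be in (0, 1), got {self.effect_fraction_q}"
            )


def _as_query(q: "float | ECxQuery") -> ECxQuery:
    return q if isinstance(q, ECxQuery) else ECxQuery(float(q))


def nec_survival_prob(params: NECParams, x):
    """Survival probability of the threshold curve at concentration(s) ``x``.

    Returns ``l * exp(-m * (x - c))`` for ``x > c`` and ``l`` otherwise;
    continuous at ``x == c``.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ParameterDomainError("concentration must be >= 0")
    p = params.intercept_l * np.exp(
        -params.slope_m * np.maximum(xs - params.threshold_c, 0.0)
    )
    return p if xs.ndim else float(p)


def loglogistic_survival_prob(params: LogLogisticParams, x):
    """Survival probability of the log-logistic curve at concentration(s) ``x``.

    ``d / (1 + exp(b * (ln x - ln e)))``; at ``x == 0`` the limit ``d`` is
    returned.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ParameterDomainError("concentration must be >= 0")
    d, b, e = params.intercept_d, params.slope_b, params.inflection_e
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(xs > 0, xs / e, 1.0)
        p = np.where(xs > 0, d / (1.0 + ratio**b), d)
    return p if xs.ndim else float(p)


def analytic_ecx_nec(params: NECParams, q) -> float:
    """Exact ECx of the threshold curve: ``c + ln(1/(1-q)) / m``."""
    qq = _as_query(q).effect_fraction_q
    return params.threshold_c - np.log1p(-qq) / params.slope_m


def analytic_ecx_loglogistic(params: LogLogisticParams, q) -> float:
    """Exact ECx of the log-logistic curve: ``e * (q/(1-q))**(1/b)``."""
    qq = _as_query(q).effect_fraction_q
    return params.inflection_e * (qq / (1.0 - qq)) ** (1.0 / params.slope_b)


def matched_loglogistic_from_nec(nec: NECParams, slope_b: float) -> LogLogisticParams:
    """Build the log-logistic curve matched to a threshold curve: same
    intercept, the given slope, and inflection equal to the threshold
    curve's exact EC50 (so the two families cross at 50% relative effect)."""
    return LogLogisticParams(
        intercept_d=nec.intercept_l,
        slope_b=float(slope_b),
        inflection_e=analytic_ecx_nec(nec, 0.5),
    )
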