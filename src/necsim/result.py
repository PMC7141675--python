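"""Shared fit-result container used by every fitter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult", "WIDE_CI_LIMIT_FRACTION", "ci_too_wide"]

# Exclusion rule: a confidence/credible interval wider than 100 percentage
# points on the percent concentration scale flags a fit as unusable.
WIDE_CI_LIMIT_FRACTION = 1.0


def ci_too_wide(lower: float, upper: float) -> bool:
    """True when a CI on the concentration-fraction scale exceeds 100
    percentage points (the proxy for very poor model fit). NaN bounds do
    not trigger the rule."""
    if not (np.isfinite(lower) and np.isfinite(upper)):
        return False
    return (upper - lower) > WIDE_CI_LIMIT_FRACTION


@dataclass
class FitResult:
    """Estimates and bookkeeping for one fitted model.

    ``ecx_estimates`` maps an effect fraction ``q`` to a
    ``(point, ci_lower, ci_upper)`` triple on the concentration-fraction
    scale. ``excluded`` is True when the fit did not converge or any
    reported interval trips the wide-CI rule; ``exclusion_reason`` says why.
    ``extras`` carries model-specific diagnostics (posterior summaries,
    rejection counts, Hessian flags, ...).
    """

    model_tag: str
    estimates: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    loglik: float = float("nan")
    n_params: int = 0
    converged: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None
    ecx_estimates: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def exclude(self, reason: str) -> "FitResult":
        self.excluded = True
        if self.exclusion_reason is None:
            self.exclusion_reason = reason
        return self

    def apply_wide_ci_rule(self, intervals) -> "FitResult":
        """Apply the wide-CI exclusion rule to an iterable of
        ``(lower, upper)`` pairs on the fraction scale."""
        for lower, upper in intervals:
            if ci_too_wide(lower, upper):
                self.exclude("wide_confidence_interval")
                break
        return self

    def to_record(self) -> dict:
        rec = {
            "model_tag": self.model_tag,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }
        for name, value in self.estimates.items():
            rec[f"est_{name}"] = value
        for name, value in self.standard_errors.items():
            rec[f"se_{name}"] = value
        for q, (pt, lo, hi) in self.ecx_estimates.items():
            tag = f"ec{round(q * 100):d}"
            rec[f"{tag}_point"] = pt
            rec[f"{tag}_lower"] = lo
            rec[f"{tag}_upper"] = hi
        return rec
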