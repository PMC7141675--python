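"""Scenario-level aggregation: RMSE, RMSE ratios, empirical HDIs,
exclusion counts, and true/spurious threshold-selection rates.

RMSE is reported on the percent-concentration scale to match the printed
study results; ratios are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import analytic_ecx_loglogistic
from .nec_bayes import hdi
from .simulate import TRUE_THRESHOLD, Scenario

__all__ = [
    "ScenarioSummary",
    "rmse",
    "rmse_ratio",
    "apparent_threshold_truth",
    "selection_rates",
    "summarize_estimates",
]


def rmse(estimates, truth: float) -> float:
    """Root-mean-square deviation of estimates from the true value."""
    est = np.asarray(estimates, float)
    if est.size == 0:
        raise ValueError("rmse requires at least one estimate")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def rmse_ratio(rmse_categorical: float, rmse_continuous: float) -> float:
    """Categorical / continuous RMSE; values above 1 favor the continuous
    design."""
    if rmse_continuous == 0:
        raise ZeroDivisionError("continuous-design RMSE is zero")
    return float(rmse_categorical) / float(rmse_continuous)


def apparent_threshold_truth(scenario: Scenario, mode: str = "nec_threshold") -> float:
    """True (or apparent) threshold of a scenario on the fraction scale.

    For threshold-family scenarios this is the generating threshold. For
    log-logistic scenarios the default convention assigns the same apparent
    threshold (0.20); the alternative ``mode='ec5'`` uses the curve's true
    EC5 instead (implemented but off by default).
    """
    if scenario.curve_family == "nec":
        return TRUE_THRESHOLD
    if mode == "nec_threshold":
        return TRUE_THRESHOLD
    if mode == "ec5":
        return analytic_ecx_loglogistic(scenario.generating_params(), 0.05)
    raise ValueError(f"unknown apparent-threshold mode: {mode!r}")


def selection_rates(selection_results):
    """Fractions of comparisons that (a) selected the threshold model by
    minimum criterion and (b) gave it strong evidence (weight >= 0.9)."""
    results = list(selection_results)
    if not results:
        raise ValueError("no selection results")
    sel = np.array([r.selected == "threshold" for r in results])
    strong = np.array([r.strong_evidence for r in results])
    return float(sel.mean()), float(strong.mean())


@dataclass
class ScenarioSummary:
    """Distributional summary of one (scenario, method, target) cell."""

    scenario_key: str
    method: str
    target: str
    truth_percent: float
    n_fitted: int
    n_excluded: int
    n_failed: int
    mean_percent: float
    rmse_percent: float
    hdi95_percent: tuple
    selection_rate: float = float("nan")
    strong_weight_rate: float = float("nan")
    estimates_percent: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_record(self) -> dict:
        rec = {
            "scenario": self.scenario_key,
            "method": self.method,
            "target": self.target,
            "truth_percent": self.truth_percent,
            "n_fitted": self.n_fitted,
            "n_excluded": self.n_excluded,
            "n_failed": self.n_failed,
            "mean_percent": self.mean_percent,
            "rmse_percent": self.rmse_percent,
            "hdi95_lower_percent": self.hdi95_percent[0],
            "hdi95_upper_percent": self.hdi95_percent[1],
            "selection_rate": self.selection_rate,
            "strong_weight_rate": self.strong_weight_rate,
        }
        return rec


def summarize_estimates(
    scenario_key: str,
    method: str,
    target: str,
    estimates_fraction,
    truth_fraction: float,
    n_excluded: int,
    n_failed: int = 0,
    selection_results=None,
) -> ScenarioSummary:
    """Aggregate per-dataset point estimates (fraction scale) into a
    percent-scale summary. Excluded fits must already be dropped from
    ``estimates_fraction``; their count is reported alongside so
    survivorship stays visible."""
    est = np.asarray(estimates_fraction, float) * 100.0
    truth = truth_fraction * 100.0
    if est.size >= 100:
        interval = hdi(est, 0.95)
    elif est.size > 0:
        interval = (float(np.quantile(est, 0.025)), float(np.quantile(est, 0.975)))
    else:
        interval = (float("nan"), float("nan"))
    sel_rate = strong_rate = float("nan")
    if selection_results:
        sel_rate, strong_rate = selection_rates(selection_results)
    return ScenarioSummary(
        scenario_key=scenario_key,
        method=method,
        target=target,
        truth_percent=truth,
        n_fitted=int(est.size),
        n_excluded=int(n_excluded),
        n_failed=int(n_failed),
        mean_percent=float(est.mean()) if est.size else float("nan"),
        rmse_percent=rmse(est, truth) if est.size else float("nan"),
        hdi95_percent=interval,
        selection_rate=sel_rate,
        strong_weight_rate=strong_rate,
        estimates_percent=est,
    )
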