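"""Information-criterion comparison of threshold vs non-threshold models
and evidence weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nec_bayes import PosteriorSample

__all__ = [
    "SelectionResult",
    "aic",
    "aicc",
    "dic",
    "ic_weights",
    "compare_models",
    "STRONG_EVIDENCE_WEIGHT",
]

STRONG_EVIDENCE_WEIGHT = 0.9


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, ``2k - 2*loglik``."""
    return 2.0 * k - 2.0 * loglik


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the small-sample correction ``2k(k+1)/(n-k-1)``; ``n`` is
    the number of experimental units (binomial rows), not organisms."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


def dic(loglik_draws: np.ndarray, loglik_at_mean: float) -> float:
    """Deviance information criterion with Spiegelhalter's effective
    parameter count: ``Dbar + pD`` where ``pD = Dbar - D(posterior mean)``.
    """
    dbar = float(np.mean(-2.0 * np.asarray(loglik_draws, float)))
    d_at_mean = -2.0 * loglik_at_mean
    pd = dbar - d_at_mean
    return dbar + pd


def dic_from_posterior(dataset, posterior: PosteriorSample) -> float:
    from .nec_bayes import posterior_loglik_draws, _nec_prob, _ll3_prob
    from ._likelihood import binom_loglik, binom_loglik_const

    draws_ll = posterior_loglik_draws(dataset, posterior)
    prob_fn = _nec_prob if posterior.param_names == ("l", "m", "c") else _ll3_prob
    means = posterior.draws.reshape(-1, posterior.draws.shape[-1]).mean(axis=0)
    y = dataset.n_survived.astype(float)
    n = dataset.n_exposed.astype(float)
    ll_mean = binom_loglik(
        y, n, prob_fn(dataset.concentration, *means), binom_loglik_const(y, n)
    )
    return dic(draws_ll, ll_mean)


def ic_weights(value_a: float, value_b: float):
    """Evidence weights ``exp(-delta/2)`` normalized over the two models."""
    if not (np.isfinite(value_a) and np.isfinite(value_b)):
        raise ValueError("criterion values must be finite")
    vals = np.array([value_a, value_b])
    rel = np.exp(-(vals - vals.min()) / 2.0)
    w = rel / rel.sum()
    return float(w[0]), float(w[1])


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one threshold-vs-null comparison."""

    criterion: str
    value_threshold_model: float
    value_null_model: float

    @property
    def delta(self) -> float:
        return self.value_threshold_model - self.value_null_model

    @property
    def weight_threshold_model(self) -> float:
        return ic_weights(self.value_threshold_model, self.value_null_model)[0]

    @property
    def selected(self) -> str:
        return "threshold" if self.delta <= 0 else "null"

    @property
    def strong_evidence(self) -> bool:
        # inclusive boundary; tiny tolerance so a weight of exactly 0.9 on
        # paper is not lost to floating-point round-off
        return self.weight_threshold_model >= STRONG_EVIDENCE_WEIGHT - 1e-12

    def to_record(self) -> dict:
        return {
            "criterion": self.criterion,
            "ic_threshold": self.value_threshold_model,
            "ic_null": self.value_null_model,
            "weight_threshold": self.weight_threshold_model,
            "selected_threshold": self.selected == "threshold",
            "strong_evidence": self.strong_evidence,
        }


def compare_models(
    criterion: str, value_threshold: float, value_null: float
) -> SelectionResult:
    return SelectionResult(criterion, float(value_threshold), float(value_null))
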