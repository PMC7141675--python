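"""Scenario-grid execution: simulate -> fit -> select -> summarize, with
deterministic seeding and CSV/JSON persistence."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import apparent_threshold_truth, summarize_estimates
from .loglogistic import fit_loglogistic3
from .nec_bayes import MCMCConfig, DESK_CONFIG, fit_nec_bayes, fit_loglogistic_bayes
from .nec_mle import fit_nec_mle
from .piecewise import fit_null_logistic, fit_piecewise
from .selection import aic, aicc, compare_models, dic_from_posterior
from .simulate import Scenario, dataset_seeds, scenario_grid, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "PRESETS", "METHODS"]

METHODS = ("ecx", "nec_mle", "nec_bayes", "piecewise")


@dataclass
class StudyConfig:
    """Declarative configuration of one study run."""

    n_datasets: int = 50
    methods: tuple = METHODS
    master_seed: int = 20200408
    mcmc: MCMCConfig = field(default_factory=lambda: DESK_CONFIG)
    ecx_levels: tuple = (0.05, 0.10, 0.50)
    scenarios: list | None = None  # None -> full 36-scenario grid

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if raw.get("scenarios"):
            raw["scenarios"] = [
                Scenario(**sc, n_datasets=raw.get("n_datasets", 50))
                if "n_datasets" not in sc
                else Scenario(**sc)
                for sc in raw["scenarios"]
            ]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "ecx_levels" in raw:
            raw["ecx_levels"] = tuple(raw["ecx_levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = (
            None
            if self.scenarios is None
            else [
                {
                    "curve_family": s.curve_family,
                    "slope_class": s.slope_class,
                    "mortality_class": s.mortality_class,
                    "design": s.design,
                    "n_datasets": s.n_datasets,
                }
                for s in self.scenarios
            ]
        )
        return d


#: Ready-made configurations: "desk" for minutes-scale runs, "paper" for a
#: full-fidelity reproduction (hours-scale).
PRESETS = {
    "desk": StudyConfig(n_datasets=50, mcmc=DESK_CONFIG),
    "paper": StudyConfig(n_datasets=1000, mcmc=MCMCConfig()),
}


def _fit_one(method, dataset, config, rng):
    if method == "ecx":
        return fit_loglogistic3(dataset, ecx_levels=config.ecx_levels), None
    if method == "nec_mle":
        return fit_nec_mle(dataset, ecx_levels=config.ecx_levels), None
    if method == "nec_bayes":
        return fit_nec_bayes(dataset, config=config.mcmc, rng=rng)
    if method == "piecewise":
        return fit_piecewise(dataset), None
    raise ValueError(f"unknown method: {method!r}")


def _threshold_estimate(method, fit):
    if method == "ecx":
        return float("nan")
    if method == "nec_mle":
        return fit.estimates.get("c", float("nan"))
    if method == "nec_bayes":
        return fit.extras.get("posterior_mean", float("nan"))
    if method == "piecewise":
        return fit.estimates.get("psi", float("nan"))
    return float("nan")


def _selection_for(method, dataset, fit, posterior, config, rng):
    """Pair each threshold method with its non-threshold comparator."""
    n_units = dataset.n_units
    if method == "nec_mle":
        null = fit_loglogistic3(dataset, ecx_levels=())
        return compare_models(
            "AIC", aic(fit.loglik, fit.n_params), aic(null.loglik, null.n_params)
        )
    if method == "nec_bayes":
        if posterior is None or not fit.converged:
            return None
        null_fit, null_post = fit_loglogistic_bayes(dataset, config=config.mcmc, rng=rng)
        if not null_fit.converged:
            return None
        return compare_models(
            "DIC",
            dic_from_posterior(dataset, posterior),
            dic_from_posterior(dataset, null_post),
        )
    if method == "piecewise":
        null = fit_null_logistic(dataset)
        return compare_models(
            "AICc",
            aicc(fit.loglik, fit.n_params, n_units),
            aicc(null.loglik, null.n_params, n_units),
        )
    return None


def run_study(config: StudyConfig, out_dir=None):
    """Execute the configured scenario grid.

    Returns ``(per_dataset, per_scenario)`` data frames; when ``out_dir``
    is given, also writes ``datasets.csv``, ``summary.csv`` and a
    ``manifest.json`` with the config. Per-dataset failures are recorded,
    never fatal.
    """
    scenarios = config.scenarios or scenario_grid(config.n_datasets)
    rows = []
    summaries = []
    for scenario in scenarios:
        rows_sc, summaries_sc = _run_scenario(scenario, config)
        rows.extend(rows_sc)
        summaries.extend(summaries_sc)

    per_dataset = pd.DataFrame(rows)
    per_scenario = pd.DataFrame([s.to_record() for s in summaries])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_dataset.to_csv(out / "datasets.csv", index=False, float_format="%.8g")
        per_scenario.to_csv(out / "summary.csv", index=False, float_format="%.8g")
        manifest = {"config": config.to_dict(), "necsim_version": __version__}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return per_dataset, per_scenario


def _run_scenario(scenario: Scenario, config: StudyConfig):
    rows = []
    collected = {m: {"estimates": [], "excluded": 0, "failed": 0, "sel": []} for m in config.methods}
    ecx_collected = {q: {"estimates": [], "excluded": 0} for q in config.ecx_levels}
    truth_threshold = apparent_threshold_truth(scenario)

    for i, seed in enumerate(dataset_seeds(scenario, config.master_seed)):
        dataset = simulate_dataset(scenario, seed)
        # independent per-dataset stream for stochastic fitters
        fit_rng = np.random.default_rng(seed.spawn(1)[0])
        for method in config.methods:
            row = {
                "dataset_id": f"{scenario.key}-{i}",
                "curve_family": scenario.curve_family,
                "slope_class": scenario.slope_class,
                "mortality_class": scenario.mortality_class,
                "design": scenario.design,
                "method": method,
            }
            try:
                fit, posterior = _fit_one(method, dataset, config, fit_rng)
            except Exception as exc:  # noqa: BLE001 - grid must not abort
                logger.warning("fit failed for %s (%s): %s", row["dataset_id"], method, exc)
                collected[method]["failed"] += 1
                row.update({"failed": True, "error": str(exc)})
                rows.append(row)
                continue
            row["failed"] = False
            row.update(fit.to_record())
            est = _threshold_estimate(method, fit)
            row["threshold_estimate"] = est
            if method == "ecx":
                for q in config.ecx_levels:
                    if fit.excluded or q not in fit.ecx_estimates:
                        ecx_collected[q]["excluded"] += 1
                    else:
                        ecx_collected[q]["estimates"].append(fit.ecx_estimates[q][0])
            if fit.excluded:
                collected[method]["excluded"] += 1
            elif method != "ecx":
                collected[method]["estimates"].append(est)
            sel = None
            if method != "ecx" and not fit.excluded:
                try:
                    sel = _selection_for(method, dataset, fit, posterior, config, fit_rng)
                except Exception as exc:  # noqa: BLE001
                    logger.warning("selection failed for %s (%s): %s", row["dataset_id"], method, exc)
            if sel is not None:
                collected[method]["sel"].append(sel)
                row.update(sel.to_record())
            rows.append(row)

    summaries = []
    for method in config.methods:
        bucket = collected[method]
        if method == "ecx":
            for q in config.ecx_levels:
                qb = ecx_collected[q]
                truth_q = _true_ecx(scenario, q)
                summaries.append(
                    summarize_estimates(
                        scenario.key,
                        "ecx",
                        f"ec{round(q*100):d}",
                        qb["estimates"],
                        truth_q,
                        qb["excluded"],
                        bucket["failed"],
                    )
                )
            continue
        summaries.append(
            summarize_estimates(
                scenario.key,
                method,
                "threshold",
                bucket["estimates"],
                truth_threshold,
                bucket["excluded"],
                bucket["failed"],
                selection_results=bucket["sel"] or None,
            )
        )
    return rows, summaries


def _true_ecx(scenario: Scenario, q: float) -> float:
    from .curves import analytic_ecx_loglogistic, analytic_ecx_nec

    params = scenario.generating_params()
    if scenario.curve_family == "nec":
        return analytic_ecx_nec(params, q)
    return analytic_ecx_loglogistic(params, q)
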