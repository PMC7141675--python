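"""Synthetic-data stage: experimental designs, the scenario grid, and
binomial survival dataset generation with control-survival rejection
filtering.

A dataset simulates the survival of 10 organisms per experimental unit, 18
units per dataset, under one of two designs:

* ``categorical``: 6 concentration levels (0, 0.0625, 0.125, 0.25, 0.5, 1.0)
  with 3 replicate units each;
* ``continuous``: 3 replicate control units at 0 plus 15 single units at
  concentrations equally spaced on the natural-log scale from 0.0394 to 1.0.

Datasets whose mean control survival falls below 80% are rejected and
regenerated; the rejection count is recorded in the dataset provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .curves import (
    LogLogisticParams,
    NECParams,
    loglogistic_survival_prob,
    matched_loglogistic_from_nec,
    nec_survival_prob,
)

__all__ = [
    "Design",
    "Scenario",
    "SurvivalDataset",
    "DegenerateScenarioError",
    "build_design",
    "scenario_grid",
    "simulate_dataset",
    "simulate_scenario",
    "SLOPE_CLASSES",
    "MORTALITY_CLASSES",
    "CATEGORICAL_LEVELS",
    "N_ORGANISMS",
    "N_UNITS",
    "TRUE_THRESHOLD",
    "CONTROL_FILTER_MIN_MEAN",
]

N_ORGANISMS = 10
N_UNITS = 18
TRUE_THRESHOLD = 0.20
CONTROL_FILTER_MIN_MEAN = 0.80

CATEGORICAL_LEVELS = (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0)
CONTINUOUS_MIN_LEVEL = 0.0394
SLOPE_CLASSES = {"shallow": 3.0, "intermediate": 5.0, "steep": 10.0}
MORTALITY_CLASSES = {"low": 0.95, "medium": 0.90, "high": 0.85}

_FAMILY_CODES = {"nec": 0, "loglogistic": 1}
_DESIGN_CODES = {"categorical": 0, "continuous": 1}


class DegenerateScenarioError(RuntimeError):
    """Raised when the control filter rejects more datasets than the cap."""


@dataclass(frozen=True)
class Design:
    """An experimental design: an ordered tuple of unit concentrations,
    each exposing ``n_organisms`` organisms."""

    name: str
    concentrations: tuple
    n_organisms: int = N_ORGANISMS

    @property
    def n_units(self) -> int:
        return len(self.concentrations)

    @property
    def control_mask(self) -> np.ndarray:
        return np.asarray(self.concentrations) == 0.0


def build_design(name: str) -> Design:
    """Return a named design.

    Continuous levels follow ``level_k = r**(-k)`` for ``k = 0..14`` with
    ``r = (1 / 0.0394) ** (1 / 14)``; the ratio is ~2^(1/3), so the five
    nonzero categorical levels reappear (to ~2e-4).
    """
    if name == "categorical":
        conc = tuple(float(c) for c in CATEGORICAL_LEVELS for _ in range(3))
    elif name == "continuous":
        ratio = (1.0 / CONTINUOUS_MIN_LEVEL) ** (1.0 / 14.0)
        levels = sorted(ratio ** (-k) for k in range(15))
        conc = (0.0, 0.0, 0.0) + tuple(levels)
    else:
        raise ValueError(f"unknown design name: {name!r}")
    assert len(conc) == N_UNITS
    return Design(name=name, concentrations=conc)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    ``curve_family`` is ``"nec"`` or ``"loglogistic"``; ``slope_class`` and
    ``mortality_class`` name the slope value (3/5/10) and control intercept
    (0.95/0.90/0.85); ``design`` names the experimental design.
    """

    curve_family: str
    slope_class: str
    mortality_class: str
    design: str
    n_datasets: int = 1000

    def __post_init__(self) -> None:
        if self.curve_family not in _FAMILY_CODES:
            raise ValueError(f"unknown curve family: {self.curve_family!r}")
        if self.slope_class not in SLOPE_CLASSES:
            raise ValueError(f"unknown slope class: {self.slope_class!r}")
        if self.mortality_class not in MORTALITY_CLASSES:
            raise ValueError(f"unknown mortality class: {self.mortality_class!r}")
        if self.design not in _DESIGN_CODES:
            raise ValueError(f"unknown design: {self.design!r}")

    @property
    def slope(self) -> float:
        return SLOPE_CLASSES[self.slope_class]

    @property
    def intercept(self) -> float:
        return MORTALITY_CLASSES[self.mortality_class]

    @property
    def key(self) -> str:
        return (
            f"{self.curve_family}-{self.slope_class}-"
            f"{self.mortality_class}-{self.design}"
        )

    def nec_params(self) -> NECParams:
        return NECParams(
            intercept_l=self.intercept, slope_m=self.slope, threshold_c=TRUE_THRESHOLD
        )

    def generating_params(self):
        """Parameters of the curve this scenario samples from."""
        nec = self.nec_params()
        if self.curve_family == "nec":
            return nec
        return matched_loglogistic_from_nec(nec, self.slope)

    def survival_prob(self, x):
        params = self.generating_params()
        if isinstance(params, LogLogisticParams):
            return loglogistic_survival_prob(params, x)
        return nec_survival_prob(params, x)

    def seed_tuple(self) -> tuple:
        """Integers identifying this scenario for seed derivation."""
        return (
            _FAMILY_CODES[self.curve_family],
            int(self.slope),
            int(round(self.intercept * 100)),
            _DESIGN_CODES[self.design],
        )


def scenario_grid(n_datasets: int = 1000) -> list:
    """The full 2 families x 3 slopes x 3 mortalities x 2 designs grid."""
    return [
        Scenario(fam, sl, mort, des, n_datasets)
        for fam in ("nec", "loglogistic")
        for sl in ("shallow", "intermediate", "steep")
        for mort in ("low", "medium", "high")
        for des in ("categorical", "continuous")
    ]


@dataclass
class SurvivalDataset:
    """One simulated (or observed) experiment in tidy per-unit form."""

    concentration: np.ndarray
    n_exposed: np.ndarray
    n_survived: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.n_exposed = np.asarray(self.n_exposed, dtype=int)
        self.n_survived = np.asarray(self.n_survived, dtype=int)
        if not (
            len(self.concentration) == len(self.n_exposed) == len(self.n_survived)
        ):
            raise ValueError("column lengths differ")
        if np.any(self.n_survived < 0) or np.any(self.n_survived > self.n_exposed):
            raise ValueError("n_survived must be in [0, n_exposed]")

    @property
    def n_units(self) -> int:
        return len(self.concentration)

    def control_mean_survival(self) -> float:
        ctrl = self.concentration == 0.0
        if not ctrl.any():
            return float("nan")
        return float(
            self.n_survived[ctrl].sum() / self.n_exposed[ctrl].sum()
        )

    def to_frame(self, dataset_id: str = "d0") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": dataset_id,
                "unit_id": np.arange(self.n_units),
                "conc_fraction": self.concentration,
                "n_exposed": self.n_exposed,
                "n_survived": self.n_survived,
            }
        )

    def to_csv(self, path, dataset_id: str = "d0") -> None:
        self.to_frame(dataset_id).to_csv(path, index=False, float_format="%.10g")
        sidecar = Path(str(path)).with_suffix(".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str) + "\n")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None):
        return cls(
            concentration=frame["conc_fraction"].to_numpy(),
            n_exposed=frame["n_exposed"].to_numpy(),
            n_survived=frame["n_survived"].to_numpy(),
            meta=meta or {},
        )

    @classmethod
    def from_csv(cls, path):
        frame = pd.read_csv(path)
        meta = {}
        sidecar = Path(str(path)).with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls.from_frame(frame, meta=meta)


def simulate_dataset(
    scenario: Scenario, seed, max_rejections: int = 10_000
) -> SurvivalDataset:
    """Draw one dataset from the scenario's generating curve.

    Each unit's survivor count is Binomial(10, p(x)). Datasets whose mean
    control survival is below 80% are discarded and redrawn; the number of
    rejections is recorded in ``meta['n_rejected']``.
    """
    rng = np.random.default_rng(seed)
    design = build_design(scenario.design)
    conc = np.asarray(design.concentrations)
    p = scenario.survival_prob(conc)
    ctrl = design.control_mask
    n = np.full(design.n_units, design.n_organisms)

    n_rejected = 0
    while True:
        y = rng.binomial(n, p)
        if y[ctrl].mean() >= CONTROL_FILTER_MIN_MEAN * design.n_organisms:
            break
        n_rejected += 1
        if n_rejected > max_rejections:
            raise DegenerateScenarioError(
                f"control filter rejected {n_rejected} datasets for {scenario.key}"
            )
    meta = {
        "scenario": scenario.key,
        "seed": repr(seed),
        "n_rejected": n_rejected,
    }
    return SurvivalDataset(concentration=conc, n_exposed=n, n_survived=y, meta=meta)


def dataset_seeds(scenario: Scenario, master_seed: int) -> list:
    """Independent child seeds for each dataset of a scenario, derived from
    the master seed and the scenario's identity (not its position in any
    grid), so scenarios can be run jointly or separately."""
    ss = np.random.SeedSequence((int(master_seed),) + scenario.seed_tuple())
    return ss.spawn(scenario.n_datasets)


def simulate_scenario(scenario: Scenario, master_seed: int) -> Iterator[SurvivalDataset]:
    """Yield ``scenario.n_datasets`` accepted datasets, reproducibly."""
    for i, child in enumerate(dataset_seeds(scenario, master_seed)):
        ds = simulate_dataset(scenario, child)
        ds.meta["dataset_index"] = i
        yield ds
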