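import numpy as np
import pytest

from necsim import Scenario, SurvivalDataset, build_design, simulate_dataset
from necsim.curves import (
    LogLogisticParams,
    NECParams,
    loglogistic_survival_prob,
    nec_survival_prob,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noise_free_dataset(params, design_name="continuous"):
    """Dataset with survivor counts rounded from the exact curve (no
    binomial noise)."""
    design = build_design(design_name)
    x = np.asarray(design.concentrations)
    if isinstance(params, NECParams):
        p = nec_survival_prob(params, x)
    else:
        p = loglogistic_survival_prob(params, x)
    y = np.round(design.n_organisms * np.asarray(p)).astype(int)
    n = np.full(design.n_units, design.n_organisms)
    return SurvivalDataset(concentration=x, n_exposed=n, n_survived=y)


@pytest.fixture
def steep_nec_dataset():
    """One noisy dataset from the steep threshold scenario."""
    return simulate_dataset(
        Scenario("nec", "steep", "medium", "continuous", 1), seed=42
    )


@pytest.fixture
def oracle_battery():
    """Small battery of simulated datasets spanning families, designs and
    slopes, used for oracle-equivalence checks."""
    datasets = []
    seed = 1000
    for fam in ("nec", "loglogistic"):
        for des in ("categorical", "continuous"):
            for slope in ("shallow", "steep"):
                sc = Scenario(fam, slope, "medium", des, 1)
                datasets.append(simulate_dataset(sc, seed=seed))
                seed += 1
    return datasets
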