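import io

import numpy as np
import pytest

from necsim.simulate import (
    CATEGORICAL_LEVELS,
    DegenerateScenarioError,
    Scenario,
    SurvivalDataset,
    build_design,
    dataset_seeds,
    scenario_grid,
    simulate_dataset,
    simulate_scenario,
)


class TestDesigns:
    def test_categorical_layout(self):
        d = build_design("categorical")
        assert d.n_units == 18
        levels = sorted(set(d.concentrations))
        assert levels == sorted(CATEGORICAL_LEVELS)
        assert max(levels) == 1.0
        for lv in levels:
            assert sum(c == lv for c in d.concentrations) == 3

    def test_continuous_layout(self):
        d = build_design("continuous")
        assert d.n_units == 18
        conc = np.asarray(d.concentrations)
        assert (conc == 0).sum() == 3
        nonzero = np.sort(conc[conc > 0])
        assert len(nonzero) == 15
        assert nonzero[0] == pytest.approx(0.0394)
        assert nonzero[-1] == 1.0
        # equal spacing on the natural-log scale
        ratios = np.diff(np.log(nonzero))
        assert np.allclose(ratios, ratios[0])

    def test_continuous_includes_categorical_levels(self):
        conc = np.asarray(build_design("continuous").concentrations)
        for lv in (0.0625, 0.125, 0.25, 0.50, 1.0):
            assert np.min(np.abs(conc - lv)) < 5e-4

    def test_unknown_design(self):
        with pytest.raises(ValueError):
            build_design("fractional")


class TestScenarioGrid:
    def test_full_grid_has_36_cells(self):
        grid = scenario_grid()
        assert len(grid) == 36
        assert len({s.key for s in grid}) == 36

    def test_invalid_scenario_fields(self):
        with pytest.raises(ValueError):
            Scenario("weibull", "steep", "medium", "continuous")
        with pytest.raises(ValueError):
            Scenario("nec", "steep", "medium", "plaid")


class TestSimulateDataset:
    def test_below_threshold_mean_survival(self):
        # below the threshold p equals the intercept (0.95 here)
        sc = Scenario("nec", "steep", "low", "categorical", 1)
        totals = []
        for seed in range(300):
            ds = simulate_dataset(sc, seed)
            mask = ds.concentration <= 0.20
            totals.append(ds.n_survived[mask].mean())
        # conditioning on the control filter pushes the mean slightly up
        assert np.mean(totals) == pytest.approx(9.5, abs=0.1)

    def test_empirical_proportions_match_curve(self):
        # per-level empirical survival within 3 binomial SEs of the curve
        sc = Scenario("nec", "shallow", "medium", "continuous", 1)
        p_true = sc.survival_prob(np.asarray(build_design("continuous").concentrations))
        counts = np.zeros(18)
        n_rep = 1000
        for seed in range(n_rep):
            counts += simulate_dataset(sc, seed).n_survived
        phat = counts / (10 * n_rep)
        se = np.sqrt(p_true * (1 - p_true) / (10 * n_rep))
        noncontrol = np.asarray(build_design("continuous").concentrations) > 0
        assert np.all(np.abs(phat - p_true)[noncontrol] <= 3 * se[noncontrol] + 1e-12)

    def test_control_filter_enforced(self):
        sc = Scenario("nec", "shallow", "high", "categorical", 1)
        for seed in range(200):
            ds = simulate_dataset(sc, seed)
            assert ds.control_mean_survival() >= 0.80

    def test_rejections_increase_with_mortality(self):
        rejected = {}
        for mort in ("low", "high"):
            sc = Scenario("nec", "steep", mort, "categorical", 1)
            rejected[mort] = sum(
                simulate_dataset(sc, seed).meta["n_rejected"] for seed in range(400)
            )
        assert rejected["high"] > rejected["low"]

    def test_degenerate_scenario_raises(self):
        sc = Scenario("nec", "steep", "high", "categorical", 1)
        # seed 4's first draw fails the control filter
        with pytest.raises(DegenerateScenarioError):
            simulate_dataset(sc, 4, max_rejections=0)

    def test_reproducibility(self):
        sc = Scenario("loglogistic", "intermediate", "medium", "continuous", 1)
        a = simulate_dataset(sc, 99)
        b = simulate_dataset(sc, 99)
        assert np.array_equal(a.n_survived, b.n_survived)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.to_frame().to_csv(buf_a, index=False, float_format="%.10g")
        b.to_frame().to_csv(buf_b, index=False, float_format="%.10g")
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_scenario_stream_reproducible_and_distinct(self):
        sc = Scenario("nec", "steep", "medium", "continuous", 5)
        run1 = [ds.n_survived for ds in simulate_scenario(sc, 7)]
        run2 = [ds.n_survived for ds in simulate_scenario(sc, 7)]
        for a, b in zip(run1, run2):
            assert np.array_equal(a, b)
        assert not np.array_equal(run1[0], run1[1])

    def test_seed_derivation_is_scenario_identity_based(self):
        sc = Scenario("nec", "steep", "medium", "continuous", 3)
        s1 = [s.entropy for s in dataset_seeds(sc, 11)]
        s2 = [s.entropy for s in dataset_seeds(sc, 11)]
        assert s1 == s2
        other = Scenario("nec", "steep", "medium", "categorical", 3)
        assert [s.entropy for s in dataset_seeds(other, 11)] != s1

    def test_filter_preserves_noncontrol_distribution(self):
        # non-control units keep their binomial distribution conditional
        # on acceptance: compare the filtered mean at the highest
        # concentration against the unconditional curve value
        sc = Scenario("nec", "shallow", "high", "categorical", 1)
        p_top = sc.survival_prob(1.0)
        tops = []
        for seed in range(600):
            ds = simulate_dataset(sc, seed)
            tops.append(ds.n_survived[ds.concentration == 1.0].mean())
        se = np.sqrt(p_top * (1 - p_top) / (10 * 3 * 600))
        assert np.mean(tops) / 10 == pytest.approx(p_top, abs=4 * se)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        sc = Scenario("nec", "steep", "medium", "continuous", 1)
        ds = simulate_dataset(sc, 5)
        path = tmp_path / "ds.csv"
        ds.to_csv(path, dataset_id="x1")
        back = SurvivalDataset.from_csv(path)
        assert np.allclose(back.concentration, ds.concentration)
        assert np.array_equal(back.n_survived, ds.n_survived)
        assert back.meta["scenario"] == sc.key

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SurvivalDataset(
                concentration=[0.0, 0.1],
                n_exposed=[10, 10],
                n_survived=[11, 0],
            )
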