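"""Synthetic survey generator: determinism, sampling laws, scenario presets."""

import numpy as np
import pandas as pd
import pytest

from heightmort import allometry as allo
from heightmort import decomposition as dec
from heightmort import synthetic
from heightmort.config import ConfigError


def one_cell_config(m: float, n_plots: int, per_plot: float, seed: int = 5,
                    **kw) -> synthetic.SimConfig:
    """A single-group, single-height-class world for sampling-law checks."""
    return synthetic.SimConfig(
        seed=seed, n_plots=n_plots, trees_per_plot_mean=per_plot,
        group_names=("only",), species_per_group={"only": ("Abies concolor",)},
        composition_by_height={allo.SHORT: (1.0,), allo.MID: (1.0,),
                               allo.TALL: (1.0,)},
        mortality_by_cell={"only": (m, m, m)},
        height_class_probs=(1.0, 0.0, 0.0), below_min_fraction=0.0, **kw)


class TestGenerateInventory:
    def test_deterministic_under_seed(self):
        cfg = synthetic.SimConfig(seed=3)
        inv1, tr1 = synthetic.generate_inventory(cfg)
        inv2, tr2 = synthetic.generate_inventory(cfg)
        assert inv1.equals(inv2)
        assert tr1.cells.equals(tr2.cells) and tr1.trees.equals(tr2.trees)
        assert not inv1.equals(synthetic.generate_inventory(
            synthetic.SimConfig(seed=4))[0])

    def test_zero_mortality_means_no_window_deaths(self):
        cfg = synthetic.SimConfig(
            seed=2, mortality_by_cell={g: (0.0, 0.0, 0.0)
                                       for g in synthetic.GROUPS_DEFAULT})
        inv, truth = synthetic.generate_inventory(cfg)
        w0, w1 = cfg.drought_window
        assert not inv["true_death_year"].between(w0, w1).any()
        assert truth.cells["window_deaths"].eq(0).all()

    def test_window_death_fraction_follows_binomial_law(self):
        # 10,000-tree single cell at m = 0.5: fraction within 3 binomial SE
        cfg = one_cell_config(0.5, n_plots=100, per_plot=100.0)
        _, truth = synthetic.generate_inventory(cfg)
        cell = truth.cells[truth.cells.height_class == allo.SHORT].iloc[0]
        frac = cell.window_deaths / cell.n_2013
        se = np.sqrt(0.25 / cell.n_2013)
        assert abs(frac - 0.5) < 3 * se

    def test_cell_rates_converge_at_1e5(self):
        # law-of-large-numbers check for every cell at n = 10^5 trees
        cfg = synthetic.SimConfig(seed=9, n_plots=500, trees_per_plot_mean=200.0,
                                  below_min_fraction=0.0)
        _, truth = synthetic.generate_inventory(cfg)
        for _, c in truth.cells.iterrows():
            se = np.sqrt(c.true_m * (1 - c.true_m) / max(c.n_2013, 1))
            assert abs(c.window_deaths / c.n_2013 - c.true_m) < 3 * se + 1e-9

    def test_default_emulates_study_scale_and_composition(self, default_world):
        cfg, inv, truth = default_world
        n_over_5m = truth.trees.true_height_class.ne(allo.BELOW_MIN).sum()
        assert 0.8 * 5855 <= n_over_5m <= 1.2 * 5855
        # composition shifts: angiosperms dominate short classes, pines gain
        p = truth.cells.pivot(index="height_class", columns="group",
                              values="n_2013").loc[list(allo.HEIGHT_CLASSES)]
        p = p.div(p.sum(axis=1), axis=0)
        assert p["angiosperm"].is_monotonic_decreasing
        assert p["pinus"].is_monotonic_increasing

    def test_snag_background_share(self):
        # pre-window snags make up ~background_dead_fraction of standing dead
        cfg = one_cell_config(0.3, n_plots=200, per_plot=100.0,
                              background_dead_fraction=0.3)
        inv, _ = synthetic.generate_inventory(cfg)
        dead = inv[inv.status == "dead"]
        pre = (dead.true_death_year < cfg.drought_window[0]).mean()
        assert abs(pre - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(dead))

    def test_retention_only_on_dead_and_dbh_bins(self, default_world):
        _, inv, _ = default_world
        assert inv.loc[inv.status == "dead", "retention_class"].notna().all()
        assert inv.loc[inv.status == "live", "retention_class"].isna().all()
        assert (inv.dbh_class % 5 == 0).all() and (inv.dbh_class >= 0).all()

    def test_composition_length_mismatch_raises(self):
        with pytest.raises(ConfigError):
            synthetic.SimConfig(composition_by_height={
                allo.SHORT: (0.5, 0.5), allo.MID: (0.3, 0.6, 0.1),
                allo.TALL: (0.1, 0.7, 0.2)})


class TestGenerateCalibration:
    def test_study_sized_sample(self):
        cfg = synthetic.SimConfig(seed=1)
        calib = synthetic.generate_calibration(cfg, 2297)
        assert len(calib) == 2297
        assert (calib.death_year <= calib.survey_year).all()
        assert calib.retention_class.between(
            1, cfg.retention_model.n_classes).all()

    def test_single_record(self):
        calib = synthetic.generate_calibration(synthetic.SimConfig(seed=1), 1)
        assert len(calib) == 1
        assert calib.death_year.iloc[0] <= calib.survey_year.iloc[0]

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_calibration(synthetic.SimConfig(), 0)

    def test_deterministic_retention_separates_window(self):
        # step-function retention: classes 1-2 are exactly the window deaths
        cfg = synthetic.SimConfig(
            seed=6, retention_model=synthetic.RetentionModel(scale=0.0))
        calib = synthetic.generate_calibration(cfg, 3000)
        in_window = calib.death_year >= cfg.drought_window[0]
        assert (calib.loc[in_window, "retention_class"] <= 2).all()
        assert (calib.loc[~in_window, "retention_class"] >= 3).all()

        inv, _ = synthetic.generate_inventory(cfg)
        dead = inv[inv.status == "dead"]
        in_w = dead.true_death_year >= cfg.drought_window[0]
        assert (dead.loc[in_w, "retention_class"].astype(int) <= 2).all()
        assert (dead.loc[~in_w, "retention_class"].astype(int) >= 3).all()


class TestScenarios:
    def test_composition_shift_preset_is_simpson_reversal(self):
        table = synthetic.scenario_table(synthetic.SCENARIO_COMPOSITION_SHIFT)
        report = dec.detect_simpson_reversal(table)
        assert report["pooled_direction"] == "increasing"
        assert set(report["group_directions"].values()) == {"decreasing"}
        assert report["reversal"]

    def test_opposing_trends_preset(self):
        table = synthetic.scenario_table(synthetic.SCENARIO_OPPOSING_TRENDS)
        report = dec.detect_simpson_reversal(table)
        assert report["pooled_direction"] == "increasing"
        assert report["opposing_group_trends"]
        assert not report["reversal"]

    def test_two_class_hand_example(self):
        # A: m=(0.30,0.20), B: m=(0.60,0.50), p_B=(0.1,0.9) -> M=(0.33,0.47)
        spec = synthetic.ScenarioSpec(
            groups=("A", "B"), height_classes=("short", "tall"),
            proportions={"A": (0.9, 0.1), "B": (0.1, 0.9)},
            mortalities={"A": (0.30, 0.20), "B": (0.60, 0.50)})
        table = synthetic.scenario_table(spec)
        m_pooled = dec.pooled_mortality(table)
        assert m_pooled.loc["short"] == pytest.approx(0.33, abs=1e-12)
        assert m_pooled.loc["tall"] == pytest.approx(0.47, abs=1e-12)

    def test_equal_mortalities_composition_invariant(self):
        spec = synthetic.ScenarioSpec(
            groups=("A", "B"), height_classes=("short", "tall"),
            proportions={"A": (0.8, 0.2), "B": (0.2, 0.8)},
            mortalities={"A": (0.3, 0.1), "B": (0.3, 0.1)})
        m_pooled = dec.pooled_mortality(synthetic.scenario_table(spec))
        assert m_pooled.loc["short"] == pytest.approx(0.3, abs=1e-12)
        assert m_pooled.loc["tall"] == pytest.approx(0.1, abs=1e-12)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.ScenarioSpec(
                groups=("A", "B"), height_classes=("short",),
                proportions={"A": (0.5,), "B": (0.6,)},
                mortalities={"A": (0.1,), "B": (0.1,)})


class TestRecoveryCells:
    def test_structure_and_calibration(self, rng):
        trees, true_m = synthetic.generate_recovery_cells(10, 400, rng)
        assert len(true_m) == 10
        assert ((true_m >= 0.02) & (true_m <= 0.6)).all()
        dead = trees[trees.status == "dead"]
        assert dead.q.between(0, 1).all()
        assert trees.loc[trees.status == "live", "q"].isna().all()
        # q is calibrated: within each cell, the q's sum to roughly the
        # number of true in-window deaths (= n_per_cell - survivors)
        for cell, sub in dead.groupby("group", sort=True):
            live = (trees.group == cell).sum() - len(sub)
            d_true = 400 - live
            assert abs(sub.q.sum() - d_true) < 4 * np.sqrt(max(d_true, 1))


def test_truth_csv_round_trip(tmp_path, default_world):
    _, _, truth = default_world
    path = tmp_path / "truth.csv"
    synthetic.write_truth_csv(truth, path)
    back = synthetic.read_truth_csv(path)
    assert len(back.cells) == len(truth.cells)
    assert len(back.trees) == len(truth.trees)
    assert back.cells["n_2013"].astype(int).tolist() == truth.cells["n_2013"].tolist()


def test_sim_config_yaml_round_trip(tmp_path):
    import yaml

    cfg = synthetic.SimConfig(seed=42)
    data = synthetic.config_to_dict(cfg)
    path = tmp_path / "sim.yaml"
    path.write_text(yaml.safe_dump(data))
    cfg2 = synthetic.config_from_dict(yaml.safe_load(path.read_text()))
    assert cfg2 == cfg
    inv1, _ = synthetic.generate_inventory(cfg)
    inv2, _ = synthetic.generate_inventory(cfg2)
    assert inv1.equals(inv2)
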