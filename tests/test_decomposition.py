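"""Pooled-mortality algebra, standardizations, and Simpson-reversal detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heightmort import allometry as allo
from heightmort import decomposition as dec
from heightmort import synthetic


def counts_frame(n_by_class_group, d_by_class_group, classes, groups):
    rows = [{"height_class": hc, "group": g,
             "n": n_by_class_group[i][j], "d": d_by_class_group[i][j]}
            for i, hc in enumerate(classes) for j, g in enumerate(groups)]
    return pd.DataFrame(rows)


TWO_GROUP = counts_frame([[100.0, 100.0]], [[10.0, 50.0]], ["c1"], ["a", "b"])


class TestPooledMortality:
    def test_single_group(self):
        counts = counts_frame([[100.0]], [[50.0]], ["c1"], ["a"])
        assert dec.pooled_mortality(counts).loc["c1"] == pytest.approx(0.5)

    def test_count_form_equals_weighted_form(self):
        # n=(100,100), d=(10,50): M = 60/200 = 0.3 = 0.5*0.1 + 0.5*0.5
        m_counts = dec.pooled_mortality(TWO_GROUP).loc["c1"]
        p = dec.proportions(TWO_GROUP).loc["c1"]
        m = dec.group_mortalities(TWO_GROUP).loc["c1"]
        assert m_counts == pytest.approx(0.3, abs=1e-12)
        assert (p * m).sum() == pytest.approx(m_counts, abs=1e-12)

    def test_total_mortality_bound(self):
        counts = counts_frame([[30.0, 70.0]], [[30.0, 70.0]], ["c1"], ["a", "b"])
        assert dec.pooled_mortality(counts).loc["c1"] == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        counts = counts_frame([[0.0, 0.0]], [[0.0, 0.0]], ["c1"], ["a", "b"])
        with pytest.raises(ValueError):
            dec.pooled_mortality(counts)

    def test_deaths_cannot_exceed_population(self):
        bad = counts_frame([[10.0]], [[11.0]], ["c1"], ["a"])
        with pytest.raises(ValueError):
            dec.pooled_mortality(bad)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 10_000), st.floats(0, 1)),
                    min_size=2, max_size=6))
    def test_count_and_weighted_forms_agree_on_random_tables(self, cells):
        ns = np.array([n for n, _ in cells], dtype=float)
        ds = np.floor(ns * np.array([f for _, f in cells]))
        counts = counts_frame([ns], [ds], ["c1"], [f"g{j}" for j in range(len(ns))])
        m_counts = dec.pooled_mortality(counts).loc["c1"]
        p = dec.proportions(counts).loc["c1"]
        m = dec.group_mortalities(counts).loc["c1"]
        assert abs((p * m).sum() - m_counts) < 1e-12
        # convexity: M within [min m, max m]
        assert m.min() - 1e-12 <= m_counts <= m.max() + 1e-12


class TestProportions:
    def test_symmetry(self):
        counts = counts_frame([[50.0, 50.0, 50.0]], [[0, 0, 0]], ["c1"],
                              ["a", "b", "c"])
        assert np.allclose(dec.proportions(counts).loc["c1"], 1 / 3)

    def test_simple_split(self):
        counts = counts_frame([[90.0, 10.0]], [[0, 0]], ["c1"], ["a", "b"])
        assert dec.proportions(counts).loc["c1"].tolist() == [0.9, 0.1]

    def test_rows_sum_to_one(self, rng):
        ns = rng.uniform(1, 1000, size=(4, 3))
        counts = counts_frame(ns, np.zeros_like(ns),
                              [f"c{i}" for i in range(4)], list("abc"))
        assert np.allclose(dec.proportions(counts).sum(axis=1), 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        counts = counts_frame([[-1.0, 5.0]], [[0, 0]], ["c1"], ["a", "b"])
        with pytest.raises(ValueError):
            dec.proportions(counts)

    def test_2013_proportions_differ_from_all_recorded_trees(self):
        """Start-of-window proportions are not the proportions of all
        standing stems when pre-window snags are unevenly distributed."""
        # two groups, equal 2013 populations but group b carries old snags
        n2013 = counts_frame([[100.0, 100.0]], [[20.0, 50.0]], ["c1"], ["a", "b"])
        p_2013 = dec.proportions(n2013).loc["c1"]
        all_recorded = counts_frame([[100.0, 130.0]], [[0, 0]], ["c1"], ["a", "b"])
        p_all = dec.proportions(all_recorded).loc["c1"]
        assert p_2013.tolist() == [0.5, 0.5]
        assert not np.allclose(p_2013, p_all)


class TestStandardizeComposition:
    def test_own_composition_is_identity(self, rng):
        ns = rng.uniform(10, 1000, size=(3, 3))
        ds = ns * rng.uniform(0, 0.5, size=(3, 3))
        counts = counts_frame(ns, ds, list(allo.HEIGHT_CLASSES), list("abc"))
        for hc in allo.HEIGHT_CLASSES:
            own_p = dec.proportions(counts).loc[hc]
            m_std = dec.standardize_composition(counts, own_p).loc[hc]
            assert m_std == pytest.approx(dec.pooled_mortality(counts).loc[hc],
                                          abs=1e-12)

    def test_uniform_group_mortality_invariant_to_reference(self, rng):
        counts = counts_frame([[100.0, 300.0]], [[20.0, 60.0]], ["c1"], ["a", "b"])
        for _ in range(5):
            p = rng.dirichlet([1, 1])
            ref = pd.Series(p, index=["a", "b"])
            assert dec.standardize_composition(counts, ref).loc[
                "c1"] == pytest.approx(0.2, abs=1e-12)

    def test_scenario_preset_reverses_under_standardization(self):
        table = synthetic.scenario_table(synthetic.SCENARIO_COMPOSITION_SHIFT)
        observed = dec.pooled_mortality(table)
        standardized = dec.standardize_composition(
            table, dec.pooled_reference_proportions(table))
        assert dec.trend_direction(observed.to_numpy()) == "increasing"
        assert dec.trend_direction(standardized.to_numpy()) == "decreasing"
        # hand evaluation at pooled p = (0.5, 0.5)
        assert np.allclose(standardized.to_numpy(), [0.30, 0.25, 0.20], atol=1e-12)

    def test_group_order_mismatch_rejected(self):
        ref = pd.Series([0.5, 0.5], index=["x", "y"])
        with pytest.raises(ValueError):
            dec.standardize_composition(TWO_GROUP, ref)

    def test_reference_must_sum_to_one(self):
        ref = pd.Series([0.5, 0.6], index=["a", "b"])
        with pytest.raises(ValueError):
            dec.standardize_composition(TWO_GROUP, ref)


class TestStandardizeGroupMortality:
    counts = counts_frame([[800.0, 200.0], [500.0, 500.0], [200.0, 800.0]],
                          [[80.0, 20.0], [50.0, 150.0], [20.0, 480.0]],
                          list(allo.HEIGHT_CLASSES), ["a", "b"])

    def test_actual_rates_are_identity(self):
        m = dec.group_mortalities(self.counts)
        for hc in allo.HEIGHT_CLASSES:
            got = dec.standardize_group_mortality(
                self.counts, "a", pooled_m=float(m.loc[hc, "a"]))
            assert got.loc[hc] == pytest.approx(
                dec.pooled_mortality(self.counts).loc[hc], abs=1e-12)

    def test_zero_weight_group_changes_nothing(self):
        counts = counts_frame([[100.0, 0.0]], [[10.0, 0.0]], ["c1"], ["a", "b"])
        for pooled_m in (0.0, 0.5, 1.0):
            got = dec.standardize_group_mortality(counts, "b", pooled_m=pooled_m)
            assert got.loc["c1"] == pytest.approx(0.1, abs=1e-12)

    def test_flattening_focal_group_attenuates_trend(self):
        # b's mortality rises (0.1, 0.3, 0.6); pooled-b rate = 650/1500
        flat = dec.standardize_group_mortality(self.counts, "b")
        observed = dec.pooled_mortality(self.counts)
        p = dec.proportions(self.counts)
        m = dec.group_mortalities(self.counts)
        pooled_b = 650.0 / 1500.0
        for hc in allo.HEIGHT_CLASSES:
            by_hand = m.loc[hc, "a"] * p.loc[hc, "a"] + pooled_b * p.loc[hc, "b"]
            assert flat.loc[hc] == pytest.approx(by_hand, abs=1e-12)
        spread = observed.max() - observed.min()
        assert flat.max() - flat.min() < spread

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            dec.standardize_group_mortality(self.counts, "nope")


class TestSimpsonDetection:
    def test_all_increasing_no_reversal(self):
        counts = counts_frame([[100, 100], [100, 100]], [[10, 20], [30, 40]],
                              ["c1", "c2"], ["a", "b"])
        report = dec.detect_simpson_reversal(counts)
        assert not report["reversal"]
        assert report["pooled_direction"] == "increasing"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dec.detect_simpson_reversal(TWO_GROUP)

    def test_trend_direction_tolerance(self):
        assert dec.trend_direction([0.1, 0.1 + 1e-12, 0.1]) == "constant"
        assert dec.trend_direction([0.1, 0.2, 0.15]) == "non-monotone"


class TestEndToEndContrast:
    def test_default_world_truth_reproduces_headline_contrast(self, default_world):
        """The generator's realized truth shows rising pooled mortality but
        falling mortality once composition is held at the whole-population
        reference: rising overall mortality with height despite no group
        rising except the pines."""
        _, _, truth = default_world
        counts = truth.cells.rename(columns={"n_2013": "n",
                                             "window_deaths": "d"})[
            ["height_class", "group", "n", "d"]]
        observed = dec.pooled_mortality(counts)
        standardized = dec.standardize_composition(
            counts, dec.pooled_reference_proportions(counts))
        assert dec.trend_direction(observed.to_numpy()) == "increasing"
        assert dec.trend_direction(standardized.to_numpy()) != "increasing"
        assert standardized.iloc[-1] < standardized.iloc[0]
        assert observed.iloc[-1] > 1.4 * observed.iloc[0]
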