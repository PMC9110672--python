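"""Bin assignment, per-bin statistics and quadrant/co-expression counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pribin import (
    BinConfig,
    ConfigError,
    EventTable,
    StateError,
    assign_bins,
    coexpression_stats,
    compute_bin_grid,
    quadrant_stats,
)
from pribin.binning import DEFAULT_QUADRANT_LAYOUT

from .conftest import random_event_table
from .oracles import naive_bin_stats, naive_coexpression, naive_quadrants


def table_from(x, y, z, transformed=True):
    return EventTable(np.column_stack([x, y, z]).astype(float),
                      channels=["X", "Y", "Z"], transformed=transformed)


class TestAssignBins:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (0.0, 0.0, (0, 0)),
            (0.45, 0.19, (2, 0)),
            (-0.1, 0.0, (-1, 0)),
            (0.2, 0.2, (1, 1)),  # bin edges belong to the upper bin
        ],
    )
    def test_floor_indexing(self, x, y, expected):
        a = assign_bins(np.array([x]), np.array([y]), 0.2)
        assert (a.ix[0], a.iy[0]) == expected

    def test_nonfinite_events_excluded_and_counted(self):
        x = np.array([0.1, np.nan, 0.3, np.inf])
        y = np.array([0.1, 0.2, np.nan, 0.4])
        with pytest.warns(UserWarning, match="3 event"):
            a = assign_bins(x, y, 0.2)
        assert a.n_excluded == 3
        assert len(a.ix) == 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.floats(-50, 50, allow_nan=False),
        st.floats(min_value=0.01, max_value=5, allow_nan=False),
    )
    def test_partition_property(self, v, width):
        a = assign_bins(np.array([v]), np.array([v]), width)
        i = a.ix[0]
        assert i * width <= v < (i + 1) * width or v == pytest.approx((i + 1) * width)


class TestBinGrid:
    def test_hand_computed_single_bin(self):
        z = [0, 1, 2, 3, 4, 5]
        t = table_from([0.05] * 6, [0.05] * 6, z)
        cfg = BinConfig("X", "Y", "Z", z_threshold=2.5)
        grid = compute_bin_grid(t, cfg)
        row = grid.bins.loc[(0, 0)]
        assert row["n_cells"] == 6
        assert row["msi"] == pytest.approx(2.5)
        assert row["n_zpos"] == 3
        assert row["msi_pos"] == pytest.approx(4.0)
        assert row["freq_zpos"] == pytest.approx(0.5)
        assert row["displayed"]

    def test_five_cell_display_rule(self):
        # 4 cells in one bin, 5 in another
        x = [0.05] * 4 + [0.45] * 5
        t = table_from(x, [0.05] * 9, [1.0] * 9)
        grid = compute_bin_grid(t, BinConfig("X", "Y", "Z"))
        assert not grid.bins.loc[(0, 0), "displayed"]
        assert grid.bins.loc[(2, 0), "displayed"]

    def test_matches_per_event_loop_oracle(self, rng):
        t = random_event_table(rng, 10_000)
        cfg = BinConfig("X", "Y", "Z", z_threshold=1.5)
        grid = compute_bin_grid(t, cfg)
        oracle = naive_bin_stats(t.get("X"), t.get("Y"), t.get("Z"), 0.2, 1.5)
        assert set(grid.bins.index) == set(oracle)
        for key, rec in oracle.items():
            row = grid.bins.loc[key]
            assert row["n_cells"] == rec["n_cells"]
            assert row["msi"] == pytest.approx(rec["sum_z"] / rec["n_cells"], rel=1e-9)
            assert row["n_zpos"] == rec["n_zpos"]
            if rec["n_zpos"]:
                assert row["msi_pos"] == pytest.approx(
                    rec["sum_zpos"] / rec["n_zpos"], rel=1e-9
                )
            else:
                assert np.isnan(row["msi_pos"])

    def test_conservation_and_bounds(self, small_table, bin_config):
        grid = compute_bin_grid(small_table, bin_config)
        assert grid.bins["n_cells"].sum() == small_table.n_events
        assert ((grid.bins["n_zpos"] >= 0) & (grid.bins["n_zpos"] <= grid.bins["n_cells"])).all()
        assert grid.bins["freq_zpos"].between(0, 1).all()

    def test_minus_inf_threshold_degenerates_to_msi(self, small_table):
        cfg = BinConfig("X", "Y", "Z", z_threshold=-np.inf)
        grid = compute_bin_grid(small_table, cfg)
        pd.testing.assert_series_equal(
            grid.bins["msi_pos"], grid.bins["msi"], check_names=False
        )
        assert (grid.bins["freq_zpos"] == 1.0).all()

    def test_translation_covariance(self, small_table, bin_config):
        grid = compute_bin_grid(small_table, bin_config)
        shifted = EventTable(
            small_table.values + np.array([3 * 0.2, 0, 0, 0]),
            channels=small_table.channels, transformed=True,
        )
        cfg = BinConfig("X", "Y", "Z", z_threshold=bin_config.z_threshold)
        grid2 = compute_bin_grid(shifted, cfg)
        moved = grid2.bins.copy()
        moved.index = pd.MultiIndex.from_arrays(
            [moved.index.get_level_values("i") - 3, moved.index.get_level_values("j")],
            names=["i", "j"],
        )
        assert set(moved.index) == set(grid.bins.index)
        np.testing.assert_allclose(
            moved.sort_index()["msi"], grid.bins.sort_index()["msi"], rtol=1e-9
        )

    def test_event_order_invariance(self, rng, small_table, bin_config):
        perm = rng.permutation(small_table.n_events)
        shuffled = EventTable(small_table.values[perm], small_table.channels,
                              transformed=True)
        a = compute_bin_grid(small_table, bin_config).bins
        b = compute_bin_grid(shuffled, bin_config).bins
        pd.testing.assert_frame_equal(a, b, rtol=1e-12)

    def test_requires_transformed_table(self, rng):
        t = random_event_table(rng, 10)
        t = EventTable(t.values, t.channels, transformed=False)
        with pytest.raises(StateError):
            compute_bin_grid(t, BinConfig("X", "Y", "Z"))

    def test_z_equal_to_axis_warns_but_runs(self, small_table):
        with pytest.warns(UserWarning, match="degenerate"):
            grid = compute_bin_grid(small_table, BinConfig("X", "Y", "X"))
        assert grid.bins["n_cells"].sum() == small_table.n_events

    def test_missing_z_threshold_leaves_msi_available(self, small_table):
        grid = compute_bin_grid(small_table, BinConfig("X", "Y", "Z"))
        assert grid.bins["msi"].notna().all()
        assert grid.bins["n_zpos"].isna().all()

    def test_csv_export_roundtrip(self, small_table, bin_config, tmp_path):
        grid = compute_bin_grid(small_table, bin_config)
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == len(grid.bins)
        assert {"i", "j", "x_lo", "y_lo", "n_cells", "msi"} <= set(back.columns)


class TestQuadrants:
    def test_constructed_4_3_2_1_split(self):
        # thresholds at 1.0/1.0; layout: Q1 ll, Q2 lh, Q3 hh, Q4 hl
        pts = [(0, 0)] * 4 + [(0, 2)] * 3 + [(2, 2)] * 2 + [(2, 0)] * 1
        t = table_from([p[0] for p in pts], [p[1] for p in pts], [0.0] * 10)
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.0, y_threshold=1.0)
        qs = quadrant_stats(t, cfg)
        assert qs["pct_of_total"].tolist() == [40.0, 30.0, 20.0, 10.0]
        assert qs["pct_of_total"].sum() == pytest.approx(100.0)

    def test_red_percentage_within_quadrant(self):
        t = table_from([2.0, 2.0], [2.0, 2.0], [5.0, 0.0])
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.0, y_threshold=1.0,
                        z_threshold=1.0)
        qs = quadrant_stats(t, cfg)
        assert qs.loc["Q3", "pct_zpos_of_quadrant"] == pytest.approx(50.0)

    def test_empty_quadrant_reports_missing_not_zero(self):
        t = table_from([2.0], [2.0], [5.0])
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.0, y_threshold=1.0,
                        z_threshold=1.0)
        qs = quadrant_stats(t, cfg)
        assert np.isnan(qs.loc["Q1", "pct_zpos_of_quadrant"])
        assert qs.loc["Q1", "n_cells"] == 0

    def test_threshold_tie_counts_as_high(self):
        t = table_from([1.0], [1.0], [1.0])
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.0, y_threshold=1.0,
                        z_threshold=1.0)
        qs = quadrant_stats(t, cfg)
        assert qs.loc["Q3", "n_cells"] == 1
        assert qs.loc["Q3", "n_zpos"] == 1

    def test_matches_boolean_oracle(self, rng):
        t = random_event_table(rng, 5000)
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.2, y_threshold=1.8,
                        z_threshold=1.5)
        qs = quadrant_stats(t, cfg)
        oracle = naive_quadrants(t.get("X"), t.get("Y"), t.get("Z"),
                                 1.2, 1.8, 1.5, DEFAULT_QUADRANT_LAYOUT)
        for q, rec in oracle.items():
            assert qs.loc[q, "n_cells"] == rec["n_cells"]
            assert qs.loc[q, "n_zpos"] == rec["n_zpos"]
            assert qs.loc[q, "pct_of_total"] == pytest.approx(
                100 * rec["n_cells"] / t.n_events
            )
        assert qs["n_cells"].sum() == t.n_events
        assert qs["pct_of_total"].sum() == pytest.approx(100.0)

    def test_requires_thresholds(self, small_table):
        with pytest.raises(ConfigError, match="threshold"):
            quadrant_stats(small_table, BinConfig("X", "Y", "Z"))


class TestCoexpression:
    def cfg(self):
        return BinConfig("X", "Y", "Z", x_threshold=1.0, y_threshold=1.0,
                         z_threshold=1.0)

    def test_all_double_positive(self):
        t = EventTable(np.array([[2.0, 2.0, 5.0, 5.0]] * 4),
                       channels=["X", "Y", "Z", "W"], transformed=True)
        cx = coexpression_stats(t, self.cfg(), "W", 1.0)
        assert cx.loc["Q3"].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_one_cell_per_category(self):
        rows = [[2, 2, 5, 5], [2, 2, 5, 0], [2, 2, 0, 5], [2, 2, 0, 0]]
        t = EventTable(np.array(rows, dtype=float),
                       channels=["X", "Y", "Z", "W"], transformed=True)
        cx = coexpression_stats(t, self.cfg(), "W", 1.0)
        assert cx.loc["Q3"].tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_fractions_sum_to_one_and_match_oracle(self, rng):
        t = random_event_table(rng, 3000)
        cfg = BinConfig("X", "Y", "Z", x_threshold=1.5, y_threshold=1.5,
                        z_threshold=1.2)
        cx = coexpression_stats(t, cfg, "W", 1.8)
        oracle = naive_coexpression(t.get("X"), t.get("Y"), t.get("Z"), t.get("W"),
                                    1.5, 1.5, 1.2, 1.8, DEFAULT_QUADRANT_LAYOUT)
        for q in cx.index:
            n = oracle[q]["n"]
            if n == 0:
                assert cx.loc[q].isna().all()
                continue
            assert cx.loc[q].sum() == pytest.approx(1.0)
            for cat in ("z1+z2+", "z1+z2-", "z1-z2+", "z1-z2-"):
                assert cx.loc[q, cat] == pytest.approx(oracle[q][cat] / n)

    def test_empty_quadrant_is_nan(self):
        t = table_from([2.0], [2.0], [5.0])
        cx = coexpression_stats(
            EventTable(np.array([[2.0, 2.0, 5.0, 5.0]]),
                       channels=["X", "Y", "Z", "W"], transformed=True),
            self.cfg(), "W", 1.0,
        )
        assert cx.loc["Q1"].isna().all()
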