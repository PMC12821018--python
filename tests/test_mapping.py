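"""Grid building, repeat aggregation, map summaries, and time binning."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Polygon

from elastimap.mapping import (
    ElasticityMap,
    IncompleteDesignError,
    aggregate_repeats,
    assemble_map,
    bin_timeseries,
    build_grid,
    compare_halves,
    summarize_map,
)


def square(side):
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


def make_map(gray, white, keep=None, times=None, temps=None):
    ks = list(gray) + list(white)
    labels = ["gray"] * len(gray) + ["white"] * len(white)
    n = len(ks)
    df = pd.DataFrame({
        "x_um": np.arange(n, dtype=float),
        "y_um": np.zeros(n),
        "K_Pa": ks,
        "label": labels,
    })
    if keep is not None:
        df["keep"] = keep
    if times is not None:
        df["postmortem_h"] = times
    if temps is not None:
        df["temperature_C"] = temps
    return ElasticityMap(entries=df)


class TestBuildGrid:
    def test_unit_square_counts(self):
        # 1 mm square, 200 um pitch: cell centres at 100..900 um -> 5x5
        pts = build_grid(square(1000.0), 200.0)
        assert pts.shape == (25, 2)
        xs = np.unique(pts[:, 0])
        np.testing.assert_allclose(xs, [100, 300, 500, 700, 900])

    def test_row_major_x_fast(self):
        pts = build_grid(square(1000.0), 500.0)
        # centres at 250, 750 in each axis; x varies fastest
        np.testing.assert_allclose(
            pts, [[250, 250], [750, 250], [250, 750], [750, 750]])

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            build_grid(Polygon([(0, 0), (1, 1), (2, 2)]), 1.0)
        with pytest.raises(ValueError):
            build_grid(square(10.0), 0.0)

    def test_idempotent_on_convex_hull_of_points(self):
        poly = Polygon([(0, 0), (1300, 0), (1300, 900), (600, 1400), (0, 900)])
        pts = build_grid(poly, 150.0)
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        again = build_grid(hull, 150.0)
        assert {tuple(p) for p in again} == {tuple(p) for p in pts}

    def test_coarse_resolution_returns_few_or_no_points(self):
        pts = build_grid(square(100.0), 1000.0)
        assert pts.shape[1] == 2
        assert len(pts) <= 1


class TestAggregateRepeats:
    def test_mean_of_passing_values(self):
        assert aggregate_repeats([100.0, 110.0]) == pytest.approx(105.0)

    def test_keep_mask_filters_before_mean(self):
        out = aggregate_repeats([100.0, 110.0, 9000.0],
                                keep=[True, True, False])
        assert out == pytest.approx(105.0)

    def test_all_excluded_gives_nan(self):
        assert math.isnan(aggregate_repeats([100.0], keep=[False]))
        assert math.isnan(aggregate_repeats([]))


class TestSummarizeMap:
    def test_worked_medians_and_ratio(self):
        emap = make_map(gray=[2.0, 3.0, 4.0], white=[1.0, 1.0, 3.0])
        s = summarize_map(emap)
        assert s.median_K_gray == pytest.approx(3.0)
        assert s.median_K_white == pytest.approx(1.0)
        assert s.ratio == pytest.approx(3.0)
        assert (s.n_gray, s.n_white) == (3, 3)

    def test_single_compartment_ratio_missing(self):
        s = summarize_map(make_map(gray=[], white=[1.0, 2.0]))
        assert math.isnan(s.ratio)
        assert s.n_gray == 0

    def test_excluded_entries_do_not_move_the_medians(self):
        base = make_map(gray=[2.0, 3.0, 4.0], white=[1.0, 1.0, 3.0])
        spiked = make_map(gray=[2.0, 3.0, 4.0, 1e6], white=[1.0, 1.0, 3.0, 1e6],
                          keep=[True] * 3 + [False] + [True] * 3 + [False])
        a, b = summarize_map(base), summarize_map(spiked)
        assert b.median_K_gray == a.median_K_gray
        assert b.median_K_white == a.median_K_white
        assert b.ratio == a.ratio

    def test_order_and_duplication_invariance(self):
        a = summarize_map(make_map(gray=[4.0, 2.0, 3.0], white=[3.0, 1.0, 1.0]))
        b = summarize_map(make_map(gray=[2.0, 3.0, 4.0], white=[1.0, 1.0, 3.0]))
        assert a.ratio == b.ratio
        # duplicating every entry leaves the medians unchanged
        c = summarize_map(make_map(gray=[2.0, 3.0, 4.0] * 2,
                                   white=[1.0, 1.0, 3.0] * 2))
        assert c.ratio == b.ratio

    def test_ratio_scales_with_gray_compartment(self):
        base = make_map(gray=[2.0, 3.0, 4.0], white=[1.0, 1.0, 3.0])
        doubled = make_map(gray=[4.0, 6.0, 8.0], white=[1.0, 1.0, 3.0])
        assert summarize_map(doubled).ratio == pytest.approx(
            2 * summarize_map(base).ratio)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            summarize_map(make_map(gray=[1.0], white=[], keep=[False]))

    def test_timestamps_are_per_compartment_medians(self):
        emap = make_map(gray=[2.0, 3.0], white=[1.0, 1.5],
                        times=[2.0, 4.0, 6.0, 8.0])
        s = summarize_map(emap)
        assert s.median_postmortem_gray == pytest.approx(3.0)
        assert s.median_postmortem_white == pytest.approx(7.0)
        assert s.mean_postmortem == pytest.approx(5.0)


class TestAssembleMap:
    def test_joins_on_position_and_averages_repeats(self):
        results = pd.DataFrame({
            "x_um": [0.0, 0.0, 100.0], "y_um": [0.0, 0.0, 0.0],
            "K_Pa": [100.0, 110.0, 50.0], "keep": [True, True, True],
            "postmortem_h": [2.0, 2.0, 2.0], "temperature_C": [25.0] * 3,
        })
        manifest = pd.DataFrame({
            "x_um": [0.0, 0.0, 100.0], "y_um": [0.0, 0.0, 0.0],
            "curve_file": ["", "", ""],
            "label": ["gray", "gray", "white"],
        })
        emap = assemble_map(results, manifest)
        gray = emap.entries[emap.entries["label"] == "gray"]
        assert len(gray) == 1
        assert gray["K_Pa"].iloc[0] == pytest.approx(105.0)

    def test_unmatched_position_raises_with_coordinates(self):
        results = pd.DataFrame({"x_um": [0.0], "y_um": [0.0],
                                "K_Pa": [100.0], "keep": [True]})
        manifest = pd.DataFrame({"x_um": [0.0, 500.0], "y_um": [0.0, 0.0],
                                 "curve_file": ["", ""],
                                 "label": ["gray", "white"]})
        with pytest.raises(KeyError, match="500"):
            assemble_map(results, manifest)
        emap = assemble_map(results, manifest, on_missing="drop")
        assert not emap.entries[emap.entries["label"] == "white"]["keep"].any()


class TestBinTimeseries:
    def test_worked_first_bin(self):
        out = bin_timeseries([1.6, 2.0], [10.0, 20.0])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["bin_start_h"] == pytest.approx(1.5)
        assert row["mean"] == pytest.approx(15.0)
        assert row["sd"] == pytest.approx(np.std([10.0, 20.0], ddof=1))
        assert row["n"] == 2
        assert not row["underflow"]

    def test_single_record_has_no_sd(self):
        out = bin_timeseries([3.0], [42.0])
        assert out.iloc[0]["n"] == 1
        assert math.isnan(out.iloc[0]["sd"])

    def test_underflow_bin_flagged_and_counts_conserved(self):
        t = [0.5, 1.0, 1.6, 2.6, 2.7, 5.0]
        out = bin_timeseries(t, np.arange(6.0))
        assert out.iloc[0]["underflow"]
        assert out.iloc[0]["bin_start_h"] == -math.inf
        assert int(out["n"].sum()) == len(t)
        # interior empty bins are skipped, not reported as n=0
        assert (out["n"] > 0).all()

    def test_bin_edges_are_half_open(self):
        out = bin_timeseries([1.5, 2.5], [1.0, 2.0])
        assert list(out["bin_start_h"]) == [1.5, 2.5]
        assert list(out["n"]) == [1, 1]


class TestCompareHalves:
    @staticmethod
    def _pair(first_g, first_w, last_g, last_w):
        m1 = make_map(gray=[first_g] * 3, white=[first_w] * 3,
                      times=[2.0] * 6)
        m2 = make_map(gray=[last_g] * 3, white=[last_w] * 3,
                      times=[8.0] * 6)
        return [m1, m2]

    def test_identical_halves_give_unit_ratio(self):
        a = self._pair(200.0, 60.0, 150.0, 45.0)
        b = self._pair(200.0, 60.0, 150.0, 45.0)
        out = compare_halves(a, b)
        assert out["half_a"]["gray"] == pytest.approx(0.75)
        assert out["change_ratio"]["gray"] == pytest.approx(1.0)
        assert out["change_ratio"]["white"] == pytest.approx(1.0)

    def test_faster_decay_in_half_a_lowers_the_ratio(self):
        a = self._pair(200.0, 60.0, 100.0, 30.0)   # halves
        b = self._pair(200.0, 60.0, 150.0, 45.0)   # loses a quarter
        out = compare_halves(a, b)
        assert out["change_ratio"]["gray"] == pytest.approx(0.5 / 0.75)
        assert out["change_ratio"]["gray"] < 1

    def test_ordering_by_time_not_by_argument_order(self):
        a = self._pair(200.0, 60.0, 100.0, 30.0)
        out = compare_halves(list(reversed(a)), a)
        assert out["change_ratio"]["gray"] == pytest.approx(1.0)

    def test_missing_timepoint_raises(self):
        a = self._pair(200.0, 60.0, 100.0, 30.0)
        with pytest.raises(IncompleteDesignError):
            compare_halves(a[:1], a)


class TestPhantomEndToEnd:
    def test_recovers_phantom_ratio_within_ten_percent(self, indenter):
        from elastimap import (
            NoiseModel,
            make_phantom,
            process_curve,
            simulate_curve,
            true_modulus,
        )

        phantom = make_phantom("transverse")
        rng = np.random.default_rng(12345)
        noise = NoiseModel(seed=42)
        pts = build_grid(phantom.outline, 350e-6)
        rows = []
        true_by_label = {}
        for x, y in pts:
            label = phantom.compartment((x, y))
            K_true = true_modulus(phantom, (x, y))
            true_by_label[label] = K_true
            curve = simulate_curve(K_true, noise=noise, rng=rng,
                                   position=(x, y))
            fit, _, verdict = process_curve(curve, indenter=indenter)
            if verdict.keep:
                rows.append({"label": label, "K_Pa": fit.K,
                             "x_um": x * 1e6, "y_um": y * 1e6})
        df = pd.DataFrame(rows)
        emap = ElasticityMap(entries=df)
        s = summarize_map(emap)
        true_ratio = true_by_label["gray"] / true_by_label["white"]
        assert s.ratio == pytest.approx(true_ratio, rel=0.10)
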