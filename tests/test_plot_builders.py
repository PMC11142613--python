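"""Tests for the figure builders and their assertable plot specs."""

import json

import numpy as np
import pandas as pd
import pytest

from madfc.plot_builders import (
    IntervalEstimate,
    as_results_table,
    box_plot,
    classify_significance,
    heatmap,
    interval_plot,
    ma_plot,
    scale_transform,
    violin_plot,
    volcano,
)
from madfc import synthetic_data
from madfc.color_norm import ColorNormSpec
from madfc.transforms import madfc_forward, madfc_inverse

TOY = pd.DataFrame({
    "feature_id": ["a", "b", "c"],
    "fc": [4.0, 0.25, 1.0],
    "pvalue": [1e-4, 1e-3, 0.8],
    "padj": [1e-3, 5e-3, 0.9],
    "base_mean": [100.0, 10.0, 0.0],
})


class TestResultsTable:
    def test_derives_log2fc_from_fc(self):
        df = as_results_table(TOY)
        np.testing.assert_allclose(df["log2fc"], [2.0, -2.0, 0.0], atol=1e-12)

    def test_derives_fc_from_log2fc(self):
        df = as_results_table(pd.DataFrame({"log2fc": [1.0, -1.0, 0.0],
                                            "pvalue": [0.5] * 3}))
        np.testing.assert_allclose(df["fc"], [2.0, 0.5, 1.0], rtol=1e-12)

    @pytest.mark.parametrize("frame", [
        pd.DataFrame({"pvalue": [0.5]}),                       # no effect column
        pd.DataFrame({"fc": [2.0]}),                           # no pvalue
        pd.DataFrame({"fc": [2.0], "pvalue": [1.5]}),          # p out of range
        pd.DataFrame({"fc": [], "pvalue": []}),                # empty
    ])
    def test_schema_violations_raise(self, frame):
        with pytest.raises(ValueError):
            as_results_table(frame)


class TestClassification:
    def test_rule(self):
        df = pd.DataFrame({
            "log2fc": [2.0, 0.0, 3.0, -2.5, 1.01],
            "pvalue": [0.01] * 5,
            "padj": [0.05, 0.05, 0.5, 0.05, 0.05],
        })
        out = classify_significance(df, padj_max=0.1, lfc_min=1.0)
        assert list(out) == ["Up", "NS", "NS", "Down", "Up"]

    def test_missing_padj_rows_are_ns(self):
        df = pd.DataFrame({"log2fc": [3.0, 3.0], "pvalue": [1e-5, 1e-5],
                           "padj": [np.nan, 0.01]})
        assert list(classify_significance(df)) == ["NS", "Up"]

    def test_no_padj_column_warns_and_uses_pvalue(self):
        df = pd.DataFrame({"log2fc": [3.0], "pvalue": [1e-5]})
        with pytest.warns(UserWarning):
            out = classify_significance(df)
        assert list(out) == ["Up"]

    def test_fcu_threshold_units(self):
        # FC = 1.9 is below 1 log2 unit but above 0.5 FCU
        df = pd.DataFrame({"fc": [1.9], "pvalue": [1e-5], "padj": [1e-4]})
        assert list(classify_significance(df, lfc_min=1.0, units="log2")) == ["NS"]
        assert list(classify_significance(df, lfc_min=0.5, units="fcu")) == ["Up"]

    def test_scale_invariance(self, de_table):
        specs = {s: volcano(de_table, s)[1] for s in ("linear", "log2", "madfc")}
        ref = specs["linear"].class_labels
        assert specs["log2"].class_labels == ref
        assert specs["madfc"].class_labels == ref


class TestVolcanoAndMA:
    @pytest.mark.parametrize("scale, expected_x", [
        ("madfc", [3.0, -3.0, 0.0]),
        ("log2", [2.0, -2.0, 0.0]),
        ("linear", [4.0, 0.25, 1.0]),
    ])
    def test_volcano_positions(self, scale, expected_x):
        fig, spec = volcano(TOY, scale)
        np.testing.assert_allclose(spec.point_positions["x"], expected_x, atol=1e-12)
        np.testing.assert_allclose(spec.point_positions["y"],
                                   -np.log10(TOY["pvalue"]), rtol=1e-12)

    def test_ma_positions_mirror_volcano(self):
        fig, spec = ma_plot(TOY, "madfc")
        np.testing.assert_allclose(spec.point_positions["y"], [3.0, -3.0, 0.0],
                                   atol=1e-12)
        np.testing.assert_allclose(
            spec.point_positions["x"], np.log10(TOY["base_mean"] + 0.5), rtol=1e-12)

    def test_zero_base_mean_lands_at_pseudocount(self):
        fig, spec = ma_plot(TOY, "linear", pseudocount=0.5)
        assert spec.point_positions["x"][2] == pytest.approx(np.log10(0.5))

    def test_tick_spec_satisfies_axis_invariants(self, de_table):
        fig, spec = volcano(de_table, "madfc")
        ts = spec.tick_spec
        assert ts is not None
        assert np.all(np.diff(ts.positions) > 0)
        assert len(ts.positions) == len(ts.labels)
        if ts.anchor_index is not None:
            assert ts.labels[ts.anchor_index] == "1"

    def test_all_out_of_domain_raises(self):
        bad = pd.DataFrame({"fc": [-1.0, 0.0], "pvalue": [0.5, 0.5]})
        with pytest.raises(ValueError):
            volcano(bad, "madfc")

    def test_propagated_nan_positions(self):
        df = pd.DataFrame({"fc": [2.0, -3.0], "pvalue": [0.5, 0.5]})
        fig, spec = volcano(df, "madfc")
        x = spec.point_positions["x"]
        assert np.isfinite(x[0]) and np.isnan(x[1])

    def test_plotspec_json_serializable(self):
        fig, spec = volcano(TOY, "madfc")
        payload = json.loads(spec.to_json())
        assert payload["kind"] == "volcano"
        assert payload["class_labels"] == list(spec.class_labels)


class TestIntervalPlot:
    def test_endpoint_transformation(self):
        g = IntervalEstimate.from_fcu(4.0, 2.0)
        fig, spec = interval_plot([g], "madfc")
        np.testing.assert_allclose(
            [spec.summary_geometry["lower"][0], spec.summary_geometry["upper"][0]],
            [1.0, 5.0], atol=1e-12)

    def test_centered_interval_symmetric_about_zero(self):
        g = IntervalEstimate.from_fcu(1.0, 2.0)
        fig, spec = interval_plot([g], "madfc")
        np.testing.assert_allclose(
            [spec.summary_geometry["lower"][0], spec.summary_geometry["upper"][0]],
            [-2.0, 2.0], atol=1e-12)
        # under linear display the same interval is visibly asymmetric
        fig, lin = interval_plot([g], "linear")
        lo, hi = lin.summary_geometry["lower"][0], lin.summary_geometry["upper"][0]
        np.testing.assert_allclose([lo, hi], [1 / 3, 3.0], rtol=1e-12)
        assert abs((1 - lo) - (hi - 1)) > 0.1

    def test_width_preserved_across_groups(self):
        groups = synthetic_data.gen_interval_groups()
        fig, spec = interval_plot(groups, "madfc")
        widths = spec.summary_geometry["width"]
        assert np.std(widths) < 1e-9
        np.testing.assert_allclose(widths, 4.0, atol=1e-9)
        for scale in ("linear", "log2"):
            fig, other = interval_plot(groups, scale)
            assert np.std(other.summary_geometry["width"]) > 0.1

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError):
            IntervalEstimate(center_fc=2.0, lower_fc=3.0, upper_fc=4.0)
        with pytest.raises(ValueError):
            interval_plot([], "madfc")


class TestBoxPlot:
    def test_display_quartiles(self):
        # raw quartile skeleton {1/5, 1/3, 1, 3, 5} -> display {-2, 0, 2}
        vals = np.array([1 / 5, 1 / 3, 1.0, 3.0, 5.0])
        fig, spec = box_plot({"g": vals}, "madfc")
        g = spec.summary_geometry["g"]
        np.testing.assert_allclose([g["q1"], g["med"], g["q3"]], [-2, 0, 2],
                                   atol=1e-12)
        np.testing.assert_allclose([g["whislo"], g["whishi"]], [-4, 4], atol=1e-12)

    def test_log2_quartiles_unequal(self):
        vals = np.array([1 / 5, 1 / 3, 1.0, 3.0, 5.0])
        fig, spec = box_plot({"g": vals}, "log2")
        g = spec.summary_geometry["g"]
        np.testing.assert_allclose([g["q1"], g["med"], g["q3"]],
                                   [-np.log2(3), 0.0, np.log2(3)], atol=1e-12)
        # box halves equal here, but whisker-to-box ratio differs from MAD
        assert g["whishi"] - g["q3"] != pytest.approx(g["q3"] - g["med"], abs=1e-3)

    def test_quantile_commutation(self):
        """transform(quantile(raw)) == quantile(transform(raw)) for monotone scales."""
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(0, 1, 501))
        for scale in ("linear", "log2", "madfc"):
            t = scale_transform(scale)
            direct = np.quantile(t(vals), [0.25, 0.5, 0.75])
            commuted = t(np.quantile(vals, [0.25, 0.5, 0.75]))
            np.testing.assert_allclose(commuted, direct, atol=1e-9)

    def test_constant_group_zero_height_box(self):
        fig, spec = box_plot({"g": np.full(6, 3.0)}, "madfc")
        g = spec.summary_geometry["g"]
        assert g["q1"] == g["med"] == g["q3"] == pytest.approx(2.0)

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            box_plot({"g": [1.0, 2.0]}, "madfc")


class TestViolinPlot:
    def test_translated_groups_have_identical_shape_under_madfc(self):
        groups = synthetic_data.gen_violin_groups(centers_fcu=[-3.0, 2.0],
                                                  n=100, seed=5)
        fig, spec = violin_plot(groups, "madfc")
        (g1, g2) = spec.summary_geometry.values()
        d1, d2 = g1["density"], g2["density"]
        assert np.max(np.abs(d1 - d2)) < 0.02 * d1.max()
        # grids differ only by the FCU translation
        assert np.ptp(np.diff(np.column_stack([g1["grid"], g2["grid"]]), axis=1)) < 1e-9

    def test_linear_scale_distorts_shape(self):
        groups = synthetic_data.gen_violin_groups(centers_fcu=[-3.0, 2.0],
                                                  n=100, seed=5)
        fig, spec = violin_plot(groups, "linear")
        (g1, g2) = spec.summary_geometry.values()
        assert np.max(np.abs(g1["density"] - g2["density"])) > 0.02 * g1["density"].max()

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            violin_plot({"g": np.full(12, 2.0)}, "madfc")
        with pytest.raises(ValueError):
            violin_plot({"g": [1.0] * 5}, "madfc")


class TestHeatmap:
    def test_all_ones_matrix_is_mid_palette(self):
        m = np.ones((3, 4))
        spec_in = ColorNormSpec("madfc", 0.25, 4.0, symmetric=True)
        fig, spec = heatmap(m, spec_in)
        np.testing.assert_allclose(spec.point_positions["normalized"], 0.5,
                                   atol=1e-12)

    def test_vmax_cell_saturates(self):
        m = np.array([[1.0, 4.0]])
        fig, spec = heatmap(m, ColorNormSpec("madfc", 0.25, 4.0, True))
        assert spec.point_positions["normalized"][0, 1] == pytest.approx(1.0)

    def test_reciprocal_pair_complementary(self):
        m = np.array([[3.0, 1 / 3]])
        fig, spec = heatmap(m, ColorNormSpec("madfc", 0.2, 5.0, True))
        n = spec.point_positions["normalized"]
        assert n[0, 0] + n[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_colorbar_ticks_valid(self):
        df = pd.DataFrame([[0.25, 1.0], [2.0, 4.0]], index=["p1", "p2"],
                          columns=["u1", "u4"])
        fig, spec = heatmap(df)
        ts = spec.tick_spec
        assert ts is not None and np.all(np.diff(ts.positions) > 0)
        assert ts.labels[ts.anchor_index] == "1"
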