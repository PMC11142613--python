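"""Tests for the labeled MAD axis: ticks, labels, and the matplotlib scale."""

import numpy as np
import pytest
import matplotlib.pyplot as plt

from madfc.axis_scale import (
    MadFCScale,
    format_fc_label,
    make_ticks,
    parse_fc_label,
    register_scale,
)
from madfc.transforms import madfc_forward, madfc_inverse


class TestMakeTicks:
    def test_full_span_fraction_labels(self):
        spec = make_ticks(-5, 5, max_ticks=11, style="fraction")
        assert list(spec.positions) == list(range(-5, 6))
        assert list(spec.labels) == ["1/6", "1/5", "1/4", "1/3", "1/2", "1",
                                     "2", "3", "4", "5", "6"]
        assert spec.anchor_index == 5

    def test_stride_thinning_keeps_anchor(self):
        spec = make_ticks(-5, 5, max_ticks=5, style="fraction")
        assert len(spec.positions) <= 5
        assert 0.0 in spec.positions
        assert spec.labels[spec.anchor_index] == "1"
        # stride-2 subset worked out by hand
        assert list(spec.positions) == [-4, -2, 0, 2, 4]
        assert list(spec.labels) == ["1/5", "1/3", "1", "3", "5"]

    def test_subunit_range_falls_back_to_decimal(self):
        spec = make_ticks(-0.5, 0.5, max_ticks=5, style="decimal")
        assert 0.0 in spec.positions
        assert spec.labels[spec.anchor_index] == "1"
        assert len(spec.positions) == 5

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError):
            make_ticks(2, 2, 5)
        with pytest.raises(ValueError):
            make_ticks(-1, 1, 2)

    def test_positions_strictly_increasing(self):
        for lo, hi, mt in [(-5, 5, 11), (-12.3, 7.8, 7), (0.2, 9.9, 4), (-0.4, 0.3, 5)]:
            spec = make_ticks(lo, hi, mt)
            assert np.all(np.diff(spec.positions) > 0)
            assert len(spec.positions) == len(spec.labels)

    def test_label_readback_exact_styles(self):
        """Parsing a fraction/exponent label and re-transforming recovers the
        tick position to 1e-9 (the readability contract, made numeric)."""
        for lo, hi, mt, style in [(-5, 5, 11, "fraction"), (-5, 5, 5, "fraction"),
                                  (-12, 9, 7, "fraction")]:
            spec = make_ticks(lo, hi, mt, style)
            for pos, label in zip(spec.positions, spec.labels):
                fc = parse_fc_label(label)
                assert madfc_forward(fc) == pytest.approx(pos, abs=1e-9)

    def test_label_readback_decimal_style(self):
        """Decimal labels also parse back to their positions to 1e-9."""
        for lo, hi in [(-6.5, 3.2), (-0.5, 0.5)]:
            spec = make_ticks(lo, hi, 9, "decimal")
            for pos, label in zip(spec.positions, spec.labels):
                fc = parse_fc_label(label)
                assert madfc_forward(fc) == pytest.approx(pos, abs=1e-9)

    def test_equal_spacing_of_integer_ticks(self):
        spec = make_ticks(-5, 5, max_ticks=11)
        assert np.allclose(np.diff(spec.positions), 1.0)

    def test_mirror_ticks_are_reciprocal_pairs(self):
        spec = make_ticks(-5, 5, max_ticks=11)
        labels = dict(zip(spec.positions, spec.labels))
        for k in range(1, 6):
            up = parse_fc_label(labels[float(k)])
            down = parse_fc_label(labels[float(-k)])
            assert down == pytest.approx(1 / up, rel=1e-9)


class TestFormatLabel:
    @pytest.mark.parametrize("x, style, expected", [
        (1 / 3, "fraction", "1/3"),
        (1, "decimal", "1"),
        (1, "fraction", "1"),
        (0.4, "fraction", "0.4"),
        (6, "fraction", "6"),
        (4, "exponent", "2^2"),
        (0.25, "exponent", "2^-2"),
        (3, "exponent", "3"),  # not a power of 2 -> decimal fallback
    ])
    def test_styles(self, x, style, expected):
        assert format_fc_label(x, style) == expected

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            format_fc_label(0, "fraction")
        with pytest.raises(ValueError):
            format_fc_label(-2, "decimal")

    @pytest.mark.parametrize("label, value", [
        ("1/6", 1 / 6), ("2^-3", 0.125), ("1", 1.0), ("3.5", 3.5),
    ])
    def test_parse(self, label, value):
        assert parse_fc_label(label) == pytest.approx(value, rel=1e-12)


class TestMatplotlibScale:
    def test_registration_idempotent(self):
        assert register_scale() is MadFCScale
        assert register_scale() is MadFCScale

    def test_axis_limits_map_to_display_units(self):
        fig, ax = plt.subplots()
        ax.set_yscale("madfc")
        ax.plot([0, 1], [1 / 6, 6])
        ax.set_ylim(1 / 6, 6)
        tr = ax.yaxis.get_transform()
        np.testing.assert_allclose(tr.transform(np.array([1 / 6, 6])), [-5, 5],
                                   rtol=1e-12)

    def test_transform_round_trip(self):
        fig, ax = plt.subplots()
        ax.set_xscale("madfc")
        tr = ax.xaxis.get_transform()
        x = np.array([0.01, 0.3, 1.0, 2.7, 40.0])
        np.testing.assert_allclose(tr.inverted().transform(tr.transform(x)), x,
                                   rtol=1e-12)

    def test_default_labels_are_back_transformed(self):
        """The public scale never shows raw MAD coordinates."""
        fig, ax = plt.subplots()
        ax.set_yscale("madfc")
        ax.plot([0, 1], [1 / 6, 6])
        ax.set_ylim(1 / 6, 6)
        fig.canvas.draw()
        texts = [t.get_text() for t in ax.get_yticklabels() if t.get_text()]
        assert "1" in texts
        assert any("/" in t for t in texts)  # fractional fold-change labels
        # raw coordinates would include negative numbers; labels never do
        assert not any(t.startswith("-") for t in texts)
        for t in texts:
            assert parse_fc_label(t) > 0

    def test_nonpositive_data_masked(self):
        fig, ax = plt.subplots()
        ax.set_xscale("madfc")
        tr = ax.xaxis.get_transform()
        out = tr.transform(np.array([-1.0, 0.0, 2.0]))
        assert np.isnan(out[:2]).all() and out[2] == 1.0

    def test_degenerate_axis_gets_padding(self):
        fig, ax = plt.subplots()
        ax.set_xscale("madfc")
        ax.plot([1.0], [0.0], "o")
        fig.canvas.draw()
        lo, hi = ax.get_xlim()
        assert lo < 1.0 < hi

    def test_label_style_kwarg(self):
        fig, ax = plt.subplots()
        ax.set_yscale("madfc", label_style="exponent", max_ticks=15)
        ax.plot([0, 1], [1 / 8, 8])
        ax.set_ylim(1 / 8, 8)
        fig.canvas.draw()
        texts = [t.get_text() for t in ax.get_yticklabels() if t.get_text()]
        # ±3 FCU ticks are raw fold changes 4 and 1/4 = 2^±2
        assert "2^2" in texts and "2^-2" in texts
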