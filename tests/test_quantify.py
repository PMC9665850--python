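"""Counting, %NETs, time-course normalization, classification, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netquant as nq
from netquant.errors import (
    ConfigurationError,
    DegenerateNormalizationError,
    StateError,
    UndefinedResultError,
)

from conftest import draw_squares


def _field(dna, marker, objective="20x", **kw):
    return nq.MultiChannelField(dna=dna, marker=marker, objective=objective, **kw)


def _grid_positions(n, size, pitch, offset=10):
    """n top-left anchors on a grid with the given pitch."""
    per_row = 5
    return [
        (offset + (i // per_row) * pitch, offset + (i % per_row) * pitch)
        for i in range(n)
    ]


class TestCounting:
    def test_count_total_matches_planted_squares(self):
        # 12 squares of 144 px (>= the 100 px 20x total gate)
        pos = _grid_positions(12, 12, 50)
        dna = draw_squares((300, 300), pos, 12, 200)
        field = _field(dna, np.full_like(dna, 10))
        n, accepted = nq.count_total(field, nq.RunConfig())
        assert n == 12
        assert len(set(np.unique(accepted)) - {0}) == 12

    def test_gate_above_object_size_counts_zero(self):
        pos = _grid_positions(12, 12, 50)
        dna = draw_squares((300, 300), pos, 12, 200)  # areas 144
        field = _field(dna, np.full_like(dna, 10))
        cfg = nq.RunConfig(min_area_total=145, min_area_net=250)
        n, _ = nq.count_total(field, cfg)
        assert n == 0

    def test_blank_field(self):
        dna = np.full((200, 200), 10, dtype=np.uint8)
        field = _field(dna, dna.copy())
        cfg = nq.RunConfig()
        n, accepted = nq.count_total(field, cfg)
        assert n == 0
        result, _, report = nq.analyze_field(field, cfg)
        assert report.degenerate
        assert result.excluded
        assert np.isnan(result.percent_net)

    def test_count_nets_manual_excludes_dim_blobs(self):
        # 3 bright NET-sized blobs + 9 dim ones below the manual threshold
        bright = _grid_positions(3, 18, 60)  # 324 px each, >= 250 gate
        dim = [(r + 150, c) for r, c in _grid_positions(9, 18, 45)]
        marker = draw_squares((320, 320), bright, 18, 220)
        marker = np.maximum(marker, draw_squares((320, 320), dim, 18, 80))
        dna = draw_squares((320, 320), bright + dim, 18, 200)
        field = _field(dna, marker)
        manual = nq.RunConfig(mode="manual", manual_threshold_marker=150)
        n_manual, _ = nq.count_nets(field, manual)
        assert n_manual == 3
        # automatic thresholding also picks up the dim-but-contrasty blobs
        n_auto, _ = nq.count_nets(field, nq.RunConfig(mode="auto"))
        assert n_auto == 12

    def test_manual_mode_requires_threshold(self):
        with pytest.raises(ConfigurationError):
            nq.RunConfig(mode="manual")

    def test_empty_marker_channel(self):
        dna = draw_squares((200, 200), [(20, 20)], 15, 200)
        field = _field(dna, np.full((200, 200), 10, dtype=np.uint8))
        n, _ = nq.count_nets(field, nq.RunConfig())
        assert n == 0


class TestPercentNets:
    @pytest.mark.parametrize("n_net,n_total,expected", [(10, 40, 25.0), (0, 40, 0.0), (40, 40, 100.0)])
    def test_formula(self, n_net, n_total, expected):
        assert nq.percent_nets(n_net, n_total) == expected

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            nq.percent_nets(0, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.integers(0, 500), b=st.integers(1, 500), k=st.integers(1, 20))
    def test_scale_invariance(self, a, b, k):
        assert nq.percent_nets(k * a, k * b) == pytest.approx(nq.percent_nets(a, b))


class TestNormalizeTimecourse:
    def _rec(self, mean, area=10, label=1):
        return nq.ObjectRecord(
            label=label, area=area, centroid=(0.0, 0.0), boundary=[(0, 0)],
            sum_dna=0.0, sum_marker=mean * area,
        )

    def test_max_normalization(self):
        recs = [self._rec(m, label=i) for i, m in enumerate((10, 20, 40), 1)]
        out = nq.normalize_timecourse(recs)
        assert [r.norm_marker_intensity for r in out] == [0.25, 0.5, 1.0]

    def test_single_object_normalizes_to_one(self):
        (out,) = nq.normalize_timecourse([self._rec(7.0)])
        assert out.norm_marker_intensity == 1.0

    def test_series_wide_not_per_image(self):
        # two "time points" with maxima 40 and 8: all divided by 40
        tp1 = [self._rec(40, label=1)]
        tp2 = [self._rec(8, label=2), self._rec(4, label=3)]
        out = nq.normalize_timecourse(tp1 + tp2)
        assert [r.norm_marker_intensity for r in out] == [1.0, 0.2, 0.1]

    def test_all_zero_series_degenerate(self):
        with pytest.raises(DegenerateNormalizationError):
            nq.normalize_timecourse([self._rec(0.0)])


class TestClassify:
    def _rec(self, area, norm):
        return nq.ObjectRecord(
            label=1, area=area, centroid=(0.0, 0.0), boundary=[(0, 0)],
            sum_dna=0.0, sum_marker=0.0, norm_marker_intensity=norm,
        )

    @pytest.mark.parametrize(
        "area,norm,expected",
        [
            (300, 0.8, "net"),
            (300, 0.1, "resting"),
            (80, 0.9, "resting"),  # area gate dominates
            (250, 0.3, "net"),  # ties classify as net
        ],
    )
    def test_rule(self, area, norm, expected):
        (out,) = nq.classify_objects([self._rec(area, norm)], area_min_net=250, intensity_min_net=0.3)
        assert out.classification == expected

    def test_missing_normalization_is_state_error(self):
        rec = self._rec(300, 0.5)
        rec.norm_marker_intensity = None
        with pytest.raises(StateError):
            nq.classify_objects([rec], area_min_net=250)


class TestAggregate:
    def _res(self, fid, pct, excluded=False, stim="PMA", t=180.0):
        return nq.FieldResult(fid, t, stim, "auto", 20, int(pct / 5), pct, 1.0, excluded)

    def test_mean_and_sd_over_fovs(self):
        out = nq.aggregate([self._res(f"f{i}", p) for i, p in enumerate((20.0, 30.0, 40.0))])
        assert len(out) == 1
        assert out.loc[0, "mean_percent_net"] == pytest.approx(30.0)
        assert out.loc[0, "sd_percent_net"] == pytest.approx(10.0)
        assert out.loc[0, "n_fov"] == 3

    def test_single_fov_sd_zero(self):
        out = nq.aggregate([self._res("f0", 25.0)])
        assert out.loc[0, "mean_percent_net"] == 25.0
        assert out.loc[0, "sd_percent_net"] == 0.0

    def test_excluded_group_omitted_with_warning(self):
        results = [
            self._res("f0", 20.0, stim="PMA"),
            self._res("f1", 90.0, excluded=True, stim="ionomycin"),
        ]
        with pytest.warns(UserWarning, match="all fields excluded"):
            out = nq.aggregate(results)
        assert list(out["stimulus"]) == ["PMA"]
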