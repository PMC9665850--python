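"""Connected-component labeling, size gating and per-object measurement."""

import math

import numpy as np
import pytest

import netquant as nq
from netquant.errors import DimensionError

from oracles import flood_fill_label


def _canonical(labels):
    """Relabel by raster-scan first occurrence so labelings can be compared."""
    out = np.zeros_like(labels)
    mapping = {}
    for v in labels.ravel():
        if v != 0 and v not in mapping:
            mapping[v] = len(mapping) + 1
    for old, new in mapping.items():
        out[labels == old] = new
    return out


class TestLabelComponents:
    def test_two_separated_squares(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[1:4, 1:4] = True
        mask[1:4, 5:8] = True
        labels = nq.label_components(mask, connectivity=8)
        assert labels.max() == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert nq.label_components(mask, connectivity=4).max() == 2
        assert nq.label_components(mask, connectivity=8).max() == 1

    def test_empty_mask(self):
        labels = nq.label_components(np.zeros((6, 6), dtype=bool), connectivity=8)
        assert labels.max() == 0

    def test_labels_in_raster_scan_order(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[6, 6] = True  # later in raster order
        mask[0, 3] = True  # first foreground pixel
        mask[3, 0] = True
        labels = nq.label_components(mask, connectivity=8)
        assert labels[0, 3] == 1 and labels[3, 0] == 2 and labels[6, 6] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42 + connectivity)
        for _ in range(20):
            h, w = rng.integers(4, 33, size=2)
            mask = rng.random((h, w)) < 0.4
            got = _canonical(nq.label_components(mask, connectivity))
            want = flood_fill_label(mask, connectivity)
            np.testing.assert_array_equal(got, want)


class TestParticleFilter:
    def _labeled_areas(self, areas):
        """One horizontal run of each requested area, one per row."""
        labels = np.zeros((len(areas) * 2, max(areas) + 2), dtype=int)
        for i, a in enumerate(areas, start=1):
            labels[2 * (i - 1), 1 : 1 + a] = i
        return labels

    def test_total_cell_gate_inclusive_at_min(self):
        labels = self._labeled_areas([99, 100, 101])
        kept = nq.particle_filter(labels, min_area=100)
        surviving = set(np.unique(kept)) - {0}
        assert surviving == {2, 3}  # 100 and 101 retained, 99 rejected

    def test_10x_gate(self):
        labels = self._labeled_areas([24, 25, 500])
        kept = nq.particle_filter(labels, min_area=25)
        assert set(np.unique(kept)) - {0} == {2, 3}

    def test_identity_and_idempotence(self):
        labels = self._labeled_areas([3, 7, 20])
        np.testing.assert_array_equal(nq.particle_filter(labels, 1, math.inf), labels)
        once = nq.particle_filter(labels, 5, 10)
        np.testing.assert_array_equal(nq.particle_filter(once, 5, 10), once)

    def test_max_area_inclusive(self):
        labels = self._labeled_areas([5, 10, 11])
        kept = nq.particle_filter(labels, 1, max_area=10)
        assert set(np.unique(kept)) - {0} == {1, 2}

    def test_monotone_in_min_area(self):
        rng = np.random.default_rng(3)
        mask = rng.random((40, 40)) < 0.45
        labels = nq.label_components(mask, 8)
        counts = []
        for lo in (1, 2, 4, 8, 16):
            kept = nq.particle_filter(labels, lo)
            counts.append(len(set(np.unique(kept)) - {0}))
        assert counts == sorted(counts, reverse=True)


class TestMeasureObjects:
    def _field(self, dna, marker=None, **kw):
        marker = np.zeros_like(dna) if marker is None else marker
        return nq.MultiChannelField(dna=dna, marker=marker, field_id="t", **kw)

    def test_uniform_square(self):
        dna = np.zeros((7, 7), dtype=np.uint8)
        dna[2:5, 2:5] = 10
        labels = np.zeros((7, 7), dtype=int)
        labels[2:5, 2:5] = 1
        (rec,) = nq.measure_objects(labels, self._field(dna))
        assert rec.area == 9
        assert rec.sum_dna == 90
        assert rec.sum_marker == 0
        assert len(rec.boundary) == 8  # 3x3 square: all but the center pixel
        assert rec.centroid == (3.0, 3.0)
        assert rec.boundary[0] == (2, 2)  # topmost-then-leftmost start

    def test_single_pixel_object(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1, 2] = 1
        dna = np.zeros((4, 4), dtype=np.uint8)
        dna[1, 2] = 7
        (rec,) = nq.measure_objects(labels, self._field(dna))
        assert rec.area == 1
        assert rec.boundary == [(1, 2)]
        assert rec.centroid == (1.0, 2.0)
        assert rec.sum_dna == 7

    def test_partition_and_conservation(self):
        rng = np.random.default_rng(9)
        mask = rng.random((30, 30)) < 0.35
        dna = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        marker = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        labels = nq.label_components(mask, 8)
        records = nq.measure_objects(labels, self._field(dna, marker))
        fg = labels > 0
        assert sum(r.area for r in records) == int(fg.sum())
        assert sum(r.sum_dna for r in records) == int(dna[fg].sum())
        assert sum(r.sum_marker for r in records) == int(marker[fg].sum())
        labels_set = [r.label for r in records]
        assert len(labels_set) == len(set(labels_set))

    def test_boundary_is_subset_of_object(self):
        rng = np.random.default_rng(13)
        mask = rng.random((25, 25)) < 0.4
        dna = np.ones((25, 25), dtype=np.uint8)
        labels = nq.label_components(mask, 8)
        for rec in nq.measure_objects(labels, self._field(dna)):
            for r, c in rec.boundary:
                assert labels[r, c] == rec.label

    def test_shape_mismatch(self):
        labels = np.zeros((4, 4), dtype=int)
        field = self._field(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(DimensionError):
            nq.measure_objects(labels, field)
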