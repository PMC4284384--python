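"""Segmentation against brute-force pixel oracles and generator ground truth."""

import numpy as np
import pytest

from endokin.segmentation import (
    CellObject,
    SegmentationParams,
    build_all_regions,
    build_initial_mask,
    build_regions,
    gate_by_marker,
    segment_cells,
    segment_frame,
)
from endokin.synthetic import make_preset, simulate_series


def _disk_frame(shape, disks, value=1000.0, background=10.0):
    frame = np.full(shape, background)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r0, c0, rad) in disks:
        frame[np.hypot(rr - r0, cc - c0) <= rad] = value
    return frame


class TestInitialMask:
    def test_zero_frame_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = build_initial_mask(np.zeros((32, 32)), SegmentationParams())
        assert not mask.data.any()

    def test_fixed_threshold_pixel_exact(self):
        frame = _disk_frame((80, 80), [(20, 20, 10), (55, 55, 8)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100)
        mask = build_initial_mask(frame, params)
        assert np.array_equal(mask.data, frame >= 100)  # brute-force comparison

    def test_all_above_threshold_full_mask(self):
        frame = np.full((16, 16), 500.0)
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100)
        assert build_initial_mask(frame, params).data.all()

    def test_percentile_mode(self):
        frame = _disk_frame((60, 60), [(30, 30, 10)])
        params = SegmentationParams(threshold_mode="percentile", threshold_value=90)
        mask = build_initial_mask(frame, params)
        assert np.array_equal(mask.data, frame >= np.percentile(frame, 90))


class TestSegmentCells:
    def test_two_disjoint_disks_areas_pixel_exact(self):
        frame = _disk_frame((100, 100), [(25, 25, 10), (70, 70, 12)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100,
                                    split_touching=False)
        mask = build_initial_mask(frame, params)
        cells = segment_cells(mask, params)
        assert len(cells) == 2
        rr, cc = np.mgrid[0:100, 0:100]
        for cell, (r0, c0, rad) in zip(cells, [(25, 25, 10), (70, 70, 12)]):
            expected = int((np.hypot(rr - r0, cc - c0) <= rad).sum())
            assert cell.area_px == expected

    def test_empty_mask_empty_list(self):
        assert segment_cells(np.zeros((32, 32), bool), SegmentationParams()) == []

    def test_touching_disks_are_split(self):
        frame = _disk_frame((100, 100), [(50, 38, 12), (50, 62, 12)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100,
                                    split_touching=True)
        cells = segment_cells(build_initial_mask(frame, params), params)
        assert len(cells) == 2
        found = sorted(c.centroid[1] for c in cells)
        assert abs(found[0] - 38) <= 2 and abs(found[1] - 62) <= 2

    def test_border_exclusion_never_increases_count(self):
        frame = _disk_frame((80, 80), [(5, 40, 10), (40, 40, 10)])
        base = dict(threshold_mode="fixed", threshold_value=100)
        n_keep = len(segment_cells(
            build_initial_mask(frame, SegmentationParams(**base)),
            SegmentationParams(exclude_border=False, **base)))
        n_excl = len(segment_cells(
            build_initial_mask(frame, SegmentationParams(**base)),
            SegmentationParams(exclude_border=True, **base)))
        assert n_excl <= n_keep
        assert n_excl == 1  # the border-touching disk is dropped

    def test_deterministic_raster_labels(self):
        frame = _disk_frame((100, 100), [(70, 20, 9), (25, 60, 9)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100)
        cells = segment_cells(build_initial_mask(frame, params), params)
        # raster order: the (25, 60) disk comes first
        assert cells[0].centroid[0] < cells[1].centroid[0]
        assert [c.label for c in cells] == [1, 2]


class TestRegions:
    def test_ring_widths_invariant(self):
        with pytest.raises(ValueError):
            SegmentationParams(ring_in_px=0, ring_out_px=0)

    def test_disk_membrane_matches_enumeration_oracle(self):
        frame = _disk_frame((60, 60), [(30, 30, 10)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100,
                                    exclude_border=False, split_touching=False)
        cells = segment_cells(build_initial_mask(frame, params), params)
        region = build_regions(cells[0], params)
        # oracle: exhaustive pixel scan against the boundary pixel set
        boundary_pts = np.argwhere(cells[0].boundary)
        rr, cc = np.mgrid[0:60, 0:60]
        d = np.full((60, 60), np.inf)
        for br, bc in boundary_pts:
            d = np.minimum(d, np.hypot(rr - br, cc - bc))
        expected_mem = d <= 2
        assert np.array_equal(region.membrane_region, expected_mem)
        expected_cyt = cells[0].pixels & ~expected_mem
        assert np.array_equal(region.cytoplasm_region, expected_cyt)

    def test_partition_invariants(self, small_field_segmented):
        _, _, cells, regions = small_field_segmented
        for cell, reg in zip(cells, regions):
            assert not (reg.membrane_region & reg.cytoplasm_region).any()
            assert np.all(cell.pixels <= (reg.membrane_region | reg.cytoplasm_region))
            assert np.all(reg.cytoplasm_region <= cell.pixels)

    def test_irregular_membrane_contains_boundary(self):
        bundle = make_preset("adherent", seed=3, n_cells=4)
        series, _ = simulate_series(bundle.cells, bundle.kinetics, bundle.acq)
        cells, regions = segment_frame(series.frame("reference", 0),
                                       SegmentationParams())
        assert cells
        for cell, reg in zip(cells, regions):
            assert np.all(cell.boundary <= reg.membrane_region)

    def test_adjacent_cells_do_not_share_membrane(self):
        frame = _disk_frame((80, 120), [(40, 35, 12), (40, 65, 12)])
        params = SegmentationParams(threshold_mode="fixed", threshold_value=100,
                                    ring_out_px=4, exclude_border=False,
                                    split_touching=False)
        cells = segment_cells(build_initial_mask(frame, params), params)
        regions = build_all_regions(cells, params)
        overlap = regions[0].membrane_region & regions[1].membrane_region
        assert not overlap.any()


class TestMarkerGate:
    def test_zero_gate_retains_all(self, small_field_segmented):
        _, _, cells, _ = small_field_segmented
        marker = np.zeros(cells[0].pixels.shape)
        assert len(gate_by_marker(cells, marker, 0.0)) == len(cells)

    def test_missing_marker_channel_is_error(self, small_field_segmented):
        _, _, cells, _ = small_field_segmented
        with pytest.raises(ValueError, match="marker"):
            gate_by_marker(cells, None, 100.0)

    def test_mixed_population_gating_matches_truth(self):
        bundle = make_preset("mixed_population", seed=9, n_cells=60)
        series, truth = simulate_series(bundle.cells, bundle.kinetics, bundle.acq)
        cells, _ = segment_frame(series.frame("reference", 0), SegmentationParams())
        kept = gate_by_marker(cells, series.frame("marker", 0), 200.0)
        n_true = sum(c.marker_positive for c in bundle.cells)
        assert len(kept) == n_true
        # every retained cell sits on a truly positive cell
        for cell in kept:
            r, c = (int(round(x)) for x in cell.centroid)
            lab = truth.label_map[r, c]
            assert bundle.cells[lab - 1].marker_positive

    def test_all_negative_field_warns_and_empties(self, small_field_segmented):
        _, _, cells, _ = small_field_segmented
        marker = np.zeros(cells[0].pixels.shape)
        with pytest.warns(UserWarning, match="gate"):
            assert gate_by_marker(cells, marker, 10.0) == []


class TestGroundTruthEquivalence:
    def test_count_and_iou_against_generator(self, small_field_segmented):
        series, truth, cells, regions = small_field_segmented
        assert len(cells) == len(np.unique(truth.label_map)) - 1
        for cell in cells:
            r, c = (int(round(x)) for x in cell.centroid)
            true_lab = truth.label_map[r, c]
            assert true_lab > 0
            true_pix = truth.label_map == true_lab
            inter = (cell.pixels & true_pix).sum()
            union = (cell.pixels | true_pix).sum()
            assert inter / union >= 0.9

    def test_determinism(self, small_field):
        series, _, _, _ = small_field
        a = segment_frame(series.frame("reference", 0), SegmentationParams())
        b = segment_frame(series.frame("reference", 0), SegmentationParams())
        for ca, cb in zip(a[0], b[0]):
            assert ca.label == cb.label
            assert np.array_equal(ca.pixels, cb.pixels)
        for ra, rb in zip(a[1], b[1]):
            assert np.array_equal(ra.membrane_region, rb.membrane_region)
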