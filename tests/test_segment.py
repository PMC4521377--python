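"""Segmentation, tracking and quantification tests against planted geometry."""

import logging

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from skars.segment import (
    derive_cytoplasm,
    expand_to_cells,
    iou,
    quantify,
    segment_nuclei,
    track_nuclei,
)


def _frame_with_disks(shape, disks, value=500.0, background=0.0):
    img = np.full(shape, background)
    for center, radius in disks:
        rr, cc = draw_disk(center, radius, shape=shape)
        img[rr, cc] = value
    return img


class TestSegmentNuclei:
    def test_blank_image_yields_no_objects(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0
        assert segment_nuclei(np.full((64, 64), 7.0)).max() == 0

    def test_two_planted_nuclei_found_with_centroids(self):
        centers = [(20.0, 20.0), (45.0, 40.0)]
        img = _frame_with_disks((64, 64), [(c, 4) for c in centers])
        labels = segment_nuclei(img)
        assert labels.max() == 2
        found = sorted(
            tuple(np.argwhere(labels == k).mean(axis=0)) for k in (1, 2)
        )
        for (fy, fx), (cy, cx) in zip(found, sorted(centers)):
            assert abs(fy - cy) <= 1 and abs(fx - cx) <= 1

    def test_area_filter_removes_small_objects(self):
        img = _frame_with_disks((64, 64), [((30.0, 30.0), 1.5)])  # 9 px
        assert (img > 250).sum() == 9
        assert segment_nuclei(img, min_area=20).max() == 0


class TestExpandToCells:
    def test_recovers_planted_cell_mask(self):
        body = _frame_with_disks((96, 96), [((48.0, 48.0), 14)], value=300.0)
        nuclei = np.zeros((96, 96), dtype=np.int32)
        rr, cc = draw_disk((48.0, 48.0), 4, shape=(96, 96))
        nuclei[rr, cc] = 1
        cells = expand_to_cells(nuclei, body)
        assert iou(cells == 1, body > 150) >= 0.9

    def test_adjacent_cells_stay_disjoint_and_contain_their_nuclei(self):
        body = _frame_with_disks(
            (96, 96), [((48.0, 34.0), 12), ((48.0, 58.0), 12)], value=300.0
        )
        nuclei = np.zeros((96, 96), dtype=np.int32)
        for lab, center in ((1, (48.0, 34.0)), (2, (48.0, 58.0))):
            rr, cc = draw_disk(center, 4, shape=(96, 96))
            nuclei[rr, cc] = lab
        cells = expand_to_cells(nuclei, body)
        assert not np.any((cells == 1) & (cells == 2))
        for lab in (1, 2):
            assert (cells[nuclei == lab] == lab).all()

    def test_nucleus_without_body_signal_gets_fallback_disk(self, caplog):
        body = np.zeros((64, 64))
        nuclei = np.zeros((64, 64), dtype=np.int32)
        rr, cc = draw_disk((32.0, 32.0), 3, shape=(64, 64))
        nuclei[rr, cc] = 1
        with caplog.at_level(logging.WARNING):
            cells = expand_to_cells(nuclei, body, body_threshold=100.0)
        assert "fallback" in caplog.text
        assert (cells == 1).sum() > (nuclei == 1).sum()


class TestDeriveCytoplasm:
    @staticmethod
    def _disk_label(shape, center, radius):
        out = np.zeros(shape, dtype=np.int32)
        rr, cc = draw_disk(center, radius, shape=shape)
        out[rr, cc] = 1
        return out

    def test_pixel_count_matches_brute_force_dilation_oracle(self):
        shape = (48, 48)
        cells = self._disk_label(shape, (24.0, 24.0), 10)
        nuclei = self._disk_label(shape, (24.0, 24.0), 3)
        expand = 2
        # brute-force Minkowski dilation of the nucleus by a radius-2 disk
        grown = np.zeros(shape, dtype=bool)
        offsets = [
            (dy, dx)
            for dy in range(-expand, expand + 1)
            for dx in range(-expand, expand + 1)
            if dy * dy + dx * dx <= expand * expand
        ]
        for y, x in np.argwhere(nuclei == 1):
            for dy, dx in offsets:
                grown[y + dy, x + dx] = True
        expected_area = (cells == 1).sum() - (grown & (cells == 1)).sum()
        cyto = derive_cytoplasm(cells, nuclei, expand_px=expand)
        assert (cyto == 1).sum() == expected_area

    def test_zero_expansion_subtracts_nucleus_exactly(self):
        shape = (48, 48)
        cells = self._disk_label(shape, (24.0, 24.0), 10)
        nuclei = self._disk_label(shape, (24.0, 24.0), 3)
        cyto = derive_cytoplasm(cells, nuclei, expand_px=0)
        assert np.array_equal(cyto > 0, (cells > 0) & ~(nuclei > 0))

    def test_nucleus_covering_cell_flags_empty_cytoplasm(self, caplog):
        shape = (32, 32)
        cells = self._disk_label(shape, (16.0, 16.0), 4)
        nuclei = self._disk_label(shape, (16.0, 16.0), 4)
        with caplog.at_level(logging.WARNING):
            cyto = derive_cytoplasm(cells, nuclei, expand_px=2)
        assert (cyto == 1).sum() == 0
        assert "empty cytoplasm" in caplog.text

    def test_mismatched_labels_raise(self):
        cells = self._disk_label((32, 32), (16.0, 16.0), 6)
        nuclei = self._disk_label((32, 32), (16.0, 16.0), 2) * 5
        with pytest.raises(ValueError, match="no matching cell"):
            derive_cytoplasm(cells, nuclei)


def _nucleus_maps(positions_per_frame, shape=(64, 64), radius=3):
    maps = []
    for positions in positions_per_frame:
        labels = np.zeros(shape, dtype=np.int32)
        for lab, center in enumerate(positions, start=1):
            rr, cc = draw_disk(center, radius, shape=shape)
            labels[rr, cc] = lab
        maps.append(labels)
    return maps


class TestTrackNuclei:
    def test_stationary_nucleus_single_full_track(self):
        maps = _nucleus_maps([[(30.0, 30.0)]] * 5)
        table = track_nuclei(maps)
        assert table.track_id.nunique() == 1
        assert table.full_length.all()

    def test_two_jittering_nuclei_keep_identities(self):
        rng = np.random.default_rng(0)
        base = [(20.0, 20.0), (20.0, 50.0)]  # 30 px apart, jitter <= 2 px
        frames = [
            [(y + rng.uniform(-2, 2), x + rng.uniform(-2, 2)) for y, x in base]
            for _ in range(6)
        ]
        table = track_nuclei(_nucleus_maps(frames))
        assert table.track_id.nunique() == 2
        # object 1 (left) must stay in one track: no swaps
        for tid, group in table.groupby("track_id"):
            assert group.x.max() - group.x.min() < 10

    def test_disappearing_nucleus_marks_partial_track(self):
        frames = [[(20.0, 20.0), (40.0, 40.0)]] * 3 + [[(20.0, 20.0)]] * 2
        table = track_nuclei(_nucleus_maps(frames))
        lengths = table.groupby("track_id").frame.nunique()
        assert sorted(lengths) == [3, 5]
        partial = lengths.idxmin()
        assert not table[table.track_id == partial].full_length.any()
        assert table[table.track_id != partial].full_length.all()


class TestQuantify:
    def test_uniform_image_gives_equal_means(self):
        maps = _nucleus_maps([[(20.0, 20.0)]])
        cyto = np.zeros_like(maps[0])
        cyto[10:14, 10:14] = 1
        tracks = track_nuclei(maps)
        img = np.full((64, 64), 7.0)
        table = quantify(
            tracks, maps, [cyto], {"sensor": [img]}, [0.0], background=None
        )
        assert table.nuc_sensor.iloc[0] == pytest.approx(7.0)
        assert table.cyt_sensor.iloc[0] == pytest.approx(7.0)

    def test_planted_ratio_recovered_noise_free(self):
        shape = (64, 64)
        nuclei = _nucleus_maps([[(32.0, 32.0)]], shape=shape)
        cells = np.zeros(shape, dtype=np.int32)
        rr, cc = draw_disk((32.0, 32.0), 10, shape=shape)
        cells[rr, cc] = 1
        cyto = derive_cytoplasm(cells, nuclei[0])
        img = np.zeros(shape)
        img[cells == 1] = 100.0
        img[nuclei[0] == 1] = 300.0  # planted ratio 3
        tracks = track_nuclei(nuclei)
        table = quantify(tracks, nuclei, [cyto], {"sensor": [img]}, [0.0])
        measured = table.nuc_sensor.iloc[0] / table.cyt_sensor.iloc[0]
        assert measured == pytest.approx(3.0, rel=0.01)

    def test_empty_cytoplasm_row_is_flagged(self):
        maps = _nucleus_maps([[(20.0, 20.0)]])
        cyto = np.zeros_like(maps[0])  # no ring at all
        tracks = track_nuclei(maps)
        table = quantify(tracks, maps, [cyto], {"sensor": [np.ones((64, 64))]}, [0.0])
        assert table.empty_cytoplasm.iloc[0]
        assert np.isnan(table.cyt_sensor.iloc[0])


class TestEndToEndFidelity:
    def test_mask_iou_and_ratio_error_on_rendered_movie(self, rendered_movie, params):
        from skars.pipeline import segment_movie
        from skars.synth import planted_ratio_trace

        truth, stack = rendered_movie
        trace_table, artifacts = segment_movie(stack.channels, stack.times)
        # match each track to the planted cell under its first-frame centroid
        tracks = artifacts["tracks"]
        gt_nuc0, gt_cell0 = stack.nucleus_labels[0], stack.cell_labels[0]
        errors = []
        for tid, group in trace_table.groupby("cell_id"):
            first = tracks[(tracks.track_id == tid) & (tracks.frame == 0)].iloc[0]
            planted_label = gt_nuc0[int(round(first.y)), int(round(first.x))]
            assert planted_label > 0
            seg_nuc = artifacts["nuclei"][0] == first.label
            seg_cell = artifacts["cells"][0] == first.label
            assert iou(seg_nuc, gt_nuc0 == planted_label) >= 0.9
            assert iou(seg_cell, gt_cell0 == planted_label) >= 0.85
            planted = planted_ratio_trace(truth, planted_label - 1, params, stack.times)
            measured = group.sort_values("time_min").ratio.to_numpy()
            errors.append(np.abs(measured / planted - 1.0))
        assert np.concatenate(errors).mean() <= 0.03
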