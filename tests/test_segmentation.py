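"""Segmentation preprocessing, detection criterion, snapshot selection."""

import numpy as np
import pytest

from oostage import (SegConfig, predict_masks, preprocess_for_segmentation, region_detected,
                     select_segmenter, train_segmenter)
from oostage.metrics import detection_ratio
from oostage.records import FPB, GV
from oostage.segmentation import SegSnapshot, load_seg_snapshot, save_seg_snapshot


class TestPreprocess:
    def test_crop_and_resize_to_three_channel_square(self, rng):
        img = rng.integers(0, 256, size=(700, 700)).astype(np.uint8)
        out = preprocess_for_segmentation(img, side=512)
        assert out.shape == (512, 512, 3)
        assert 0 <= out.min() and out.max() <= 1

    def test_matching_size_identity_up_to_scaling(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        out = preprocess_for_segmentation(img, side=64)
        assert np.allclose(out[..., 0], img / 255.0)
        assert np.array_equal(out[..., 0], out[..., 1])

    def test_bounding_box_crop(self, rng):
        img = rng.integers(0, 256, size=(200, 300)).astype(np.uint8)
        out = preprocess_for_segmentation(img, (50, 100, 150, 200), side=64)
        assert out.shape == (64, 64, 3)

    def test_degenerate_box_rejected(self, rng):
        img = rng.integers(0, 256, size=(100, 100)).astype(np.uint8)
        with pytest.raises(ValueError, match="degenerate"):
            preprocess_for_segmentation(img, (10, 10, 11, 50), side=64)


class TestRegionDetected:
    def _masks(self, n_overlap):
        truth = np.zeros((64, 64), np.uint8)
        truth[:32] = 1
        pred = np.zeros((64, 64), np.uint8)
        pred.ravel()[: n_overlap] = 1
        return pred, truth

    def test_boundary_at_threshold(self):
        pred, truth = self._masks(100)
        assert region_detected(pred, truth)
        pred, truth = self._masks(99)
        assert not region_detected(pred, truth)

    def test_matches_intersection_oracle(self, rng):
        for _ in range(1000):
            pred = rng.uniform(size=(20, 20)) < 0.4
            truth = rng.uniform(size=(20, 20)) < 0.4
            want = int(np.sum(pred & truth)) >= 50
            assert region_detected(pred, truth, threshold=50) == want

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_detected(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_dr_extremes(self):
        truth = np.ones((64, 64), np.uint8)
        assert detection_ratio([region_detected(truth, truth)]) == 1.0
        assert detection_ratio([region_detected(np.zeros_like(truth), truth)]) == 0.0


class TestSelectSegmenter:
    def _snap(self, epoch, dr, miou):
        return SegSnapshot(epoch=epoch, state={}, dr=dr, iou=miou, input_side=64, base_filters=4)

    def test_lexicographic_rule(self):
        snaps = [self._snap(1, 0.8, 0.5), self._snap(2, 0.9, 0.6), self._snap(3, 0.9, 0.7)]
        assert select_segmenter(snaps).epoch == 3

    def test_single_snapshot(self):
        s = self._snap(1, 0.1, 0.1)
        assert select_segmenter([s]) is s

    def test_matches_bruteforce_lexicographic_argmax(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            drs = rng.choice([0.5, 0.75, 1.0], size=n)
            ious = rng.choice([0.2, 0.4, 0.6], size=n)
            snaps = [self._snap(i + 1, d, j) for i, (d, j) in enumerate(zip(drs, ious))]
            best = select_segmenter(snaps)
            # brute force: max (dr, iou), first occurrence
            want = max(range(n), key=lambda i: (drs[i], ious[i], -i))
            assert best.epoch == want + 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_segmenter([])


@pytest.fixture(scope="module")
def seg_smoke(small_dataset):
    records = small_dataset[0][:2] + small_dataset[0][10:12] + small_dataset[0][20:22]
    cfg = SegConfig(input_side=32, epochs=2, batch_size=3, seed=0)
    return records, train_segmenter(records, cfg)


class TestTrainSegmenter:
    def test_smoke_snapshot_metrics_finite(self, seg_smoke):
        _, snaps = seg_smoke
        assert len(snaps) == 2
        for s in snaps:
            assert 0 <= s.dr <= 1 and 0 <= s.iou <= 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], SegConfig(input_side=32, epochs=1))

    def test_predicted_masks_disjoint_and_source_shaped(self, seg_smoke):
        records, snaps = seg_smoke
        masks = predict_masks(records[0].image, snaps[-1], min_region_px=0)
        assert masks[GV].shape == records[0].image.shape
        assert not np.any(masks[GV] & masks[FPB])

    def test_untrained_snapshot_rejected(self, seg_smoke):
        records, _ = seg_smoke
        blank = SegSnapshot(epoch=0, state=None, dr=0, iou=0, input_side=32, base_filters=12)
        with pytest.raises(ValueError, match="untrained"):
            predict_masks(records[0].image, blank)

    def test_snapshot_roundtrip(self, seg_smoke, tmp_path):
        records, snaps = seg_smoke
        save_seg_snapshot(snaps[-1], tmp_path / "seg")
        loaded = load_seg_snapshot(tmp_path / "seg")
        a = predict_masks(records[0].image, snaps[-1])
        b = predict_masks(records[0].image, loaded)
        assert np.array_equal(a[GV], b[GV]) and np.array_equal(a[FPB], b[FPB])

    def test_deterministic_under_seed(self, small_dataset):
        records = small_dataset[0][:3]
        cfg = SegConfig(input_side=32, epochs=1, batch_size=3, seed=5)
        s1 = train_segmenter(records, cfg)[-1]
        s2 = train_segmenter(records, cfg)[-1]
        for k in s1.state:
            for a, b in zip(s1.state[k], s2.state[k]):
                assert np.array_equal(a, b)
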