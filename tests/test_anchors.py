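"""Anchor tiling, IoU assignment and box/keypoint coding."""

import numpy as np
import pytest

from oculoscore.detector import (
    DetectorConfig,
    assign_anchors,
    box_xywh_to_cwh,
    decode_box,
    decode_keypoints,
    encode_box,
    encode_keypoints,
    generate_anchors,
    iou_matrix,
    nms,
)
from oculoscore.detector.anchors import IGNORE, NEGATIVE, POSITIVE, feature_map_shapes


def iou_oracle(a, b):
    """Scalar corner-arithmetic IoU for one anchor/box pair (cx, cy, w, h)."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def single_level_config(**kw):
    return DetectorConfig(strides=(8,), anchor_sizes=(((16.0, 8.0), (24.0, 12.0)),), **kw)


class TestGenerateAnchors:
    def test_one_level_4x4_map_two_sizes_gives_32_anchors(self):
        cfg = single_level_config()
        anchors = generate_anchors(cfg, (32, 32))
        assert anchors.shape == (32, 4)

    def test_centers_sit_on_the_stride_lattice_offset_half_stride(self):
        cfg = single_level_config()
        anchors = generate_anchors(cfg, (32, 32))
        assert set(np.unique(anchors[:, 0])) == {4.0, 12.0, 20.0, 28.0}
        assert set(np.unique(anchors[:, 1])) == {4.0, 12.0, 20.0, 28.0}

    def test_regeneration_is_deterministic(self):
        cfg = DetectorConfig()
        a = generate_anchors(cfg, (128, 256))
        b = generate_anchors(cfg, (128, 256))
        assert np.array_equal(a, b)

    def test_feature_maps_follow_integer_division(self):
        cfg = DetectorConfig()
        assert feature_map_shapes(cfg, (128, 128)) == [(16, 16), (8, 8), (4, 4)]

    def test_indivisible_size_names_the_stride(self):
        with pytest.raises(ValueError, match="32"):
            generate_anchors(DetectorConfig(), (100, 60))


class TestAssignAnchors:
    def test_anchor_identical_to_box_is_positive(self):
        cfg = DetectorConfig()
        anchors = np.array([[50.0, 50.0, 60.0, 30.0], [200.0, 90.0, 60.0, 30.0]])
        labels, matched = assign_anchors(anchors, np.array([[50.0, 50.0, 60.0, 30.0]]), cfg)
        assert labels[0] == POSITIVE and matched[0] == 0

    def test_disjoint_anchor_is_negative(self):
        cfg = DetectorConfig()
        anchors = np.array([[200.0, 90.0, 60.0, 30.0]])
        labels, _ = assign_anchors(anchors, np.array([[50.0, 50.0, 60.0, 30.0]]), cfg)
        # argmax forcing still claims the best anchor for the ground truth
        assert labels[0] == POSITIVE
        anchors2 = np.array([[200.0, 90.0, 60.0, 30.0], [52.0, 50.0, 60.0, 30.0]])
        labels2, _ = assign_anchors(anchors2, np.array([[50.0, 50.0, 60.0, 30.0]]), cfg)
        assert labels2[0] == NEGATIVE and labels2[1] == POSITIVE

    def test_zero_ground_truth_makes_everything_negative(self):
        cfg = DetectorConfig()
        anchors = generate_anchors(cfg, (128, 256))
        labels, matched = assign_anchors(anchors, np.zeros((0, 4)), cfg)
        assert (labels == NEGATIVE).all() and (matched == -1).all()

    def test_matches_brute_force_iou_oracle(self, rng):
        cfg = DetectorConfig(iou_positive=0.5, iou_negative=0.3)
        anchors = np.column_stack(
            [rng.uniform(0, 200, 20), rng.uniform(0, 100, 20), rng.uniform(10, 80, 20), rng.uniform(10, 60, 20)]
        )
        boxes = np.column_stack(
            [rng.uniform(0, 200, 3), rng.uniform(0, 100, 3), rng.uniform(10, 80, 3), rng.uniform(10, 60, 3)]
        )
        ious = np.array([[iou_oracle(a, b) for b in boxes] for a in anchors])
        assert np.allclose(iou_matrix(anchors, boxes), ious, atol=1e-12)
        labels, matched = assign_anchors(anchors, boxes, cfg)
        expected = np.full(20, NEGATIVE)
        exp_match = np.full(20, -1)
        best = ious.argmax(axis=1)
        for i in range(20):
            if ious[i, best[i]] >= 0.5:
                expected[i], exp_match[i] = POSITIVE, best[i]
            elif ious[i, best[i]] >= 0.3:
                expected[i] = IGNORE
        for j in range(3):
            i = ious[:, j].argmax()
            expected[i], exp_match[i] = POSITIVE, j
        assert np.array_equal(labels, expected)
        assert np.array_equal(matched, exp_match)


class TestBoxCoding:
    def test_box_equal_to_anchor_encodes_to_zero(self):
        anchor = np.array([[50.0, 40.0, 64.0, 32.0]])
        assert np.allclose(encode_box(anchor, anchor), 0.0)

    def test_double_width_encodes_log_two(self):
        anchor = np.array([[50.0, 40.0, 64.0, 32.0]])
        box = np.array([[50.0, 40.0, 128.0, 32.0]])
        assert encode_box(anchor, box)[0, 2] == pytest.approx(np.log(2.0))

    def test_roundtrip_on_random_boxes(self, rng):
        anchors = np.column_stack(
            [rng.uniform(0, 200, 100), rng.uniform(0, 100, 100), rng.uniform(20, 80, 100), rng.uniform(20, 60, 100)]
        )
        boxes = np.column_stack(
            [rng.uniform(0, 200, 100), rng.uniform(0, 100, 100), rng.uniform(20, 80, 100), rng.uniform(20, 60, 100)]
        )
        back = decode_box(anchors, encode_box(anchors, boxes))
        assert np.abs(back - boxes).max() < 1e-6 * boxes[:, 2:].max()

    def test_degenerate_anchor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            encode_box(np.array([[10.0, 10.0, 0.0, 5.0]]), np.array([[10.0, 10.0, 5.0, 5.0]]))


class TestKeypointCoding:
    def test_points_at_anchor_center_encode_to_zero(self):
        anchor = np.array([[50.0, 40.0, 64.0, 32.0]])
        pts = np.array([[50.0, 40.0, 50.0, 40.0, 50.0, 40.0]])
        assert np.allclose(encode_keypoints(anchor, pts), 0.0)

    def test_roundtrip_preserves_order_and_values(self, rng):
        anchors = np.column_stack(
            [rng.uniform(0, 200, 50), rng.uniform(0, 100, 50), rng.uniform(20, 80, 50), rng.uniform(20, 60, 50)]
        )
        pts = rng.uniform(0, 200, size=(50, 6))
        back = decode_keypoints(anchors, encode_keypoints(anchors, pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_decoded_pupil_stays_between_canthi(self, rng):
        anchor = np.array([[100.0, 50.0, 64.0, 32.0]])
        pts = np.array([[70.0, 50.0, 95.0, 51.0, 130.0, 52.0]])  # lateral < pupil < medial in x
        dec = decode_keypoints(anchor, encode_keypoints(anchor, pts))[0]
        assert dec[0] < dec[2] < dec[4]


class TestNms:
    def test_duplicate_overlapping_candidates_collapse(self):
        boxes = np.array([[50.0, 50.0, 60.0, 30.0], [52.0, 50.0, 60.0, 30.0], [200.0, 50.0, 60.0, 30.0]])
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), iou_threshold=0.4)
        assert list(keep) == [0, 2]

    def test_xywh_conversion(self):
        out = box_xywh_to_cwh([(10.0, 20.0, 40.0, 20.0)])
        assert np.allclose(out, [[30.0, 30.0, 40.0, 20.0]])
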