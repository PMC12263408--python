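"""Anchor generation, IoU assignment, and box/keypoint coding.

Anchors are axis-aligned reference rectangles tiled over every feature
map cell of every pyramid level.  They are stored as ``(cx, cy, w, h)``
center/size rows in a fixed deterministic order: level-major, then row,
then column, then anchor size.  Regression targets are the standard
anchor-relative offsets: center shifts normalized by anchor size and
log-scale width/height ratios; keypoints use the same center/size
normalization.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .config import DetectorConfig

IGNORE, NEGATIVE, POSITIVE = -1, 0, 1


def feature_map_shapes(config: DetectorConfig, image_size: Tuple[int, int]):
    """(H, W) of each pyramid level's feature map."""
    h, w = image_size
    top = max(config.strides)
    if h % top or w % top:
        raise ValueError(f"image size {image_size} not divisible by the largest stride {top}")
    return [(h // s, w // s) for s in config.strides]


def generate_anchors(config: DetectorConfig, image_size: Tuple[int, int]) -> np.ndarray:
    """All anchors for an image size, as an (A, 4) array of (cx, cy, w, h)."""
    rows = []
    for (fh, fw), stride, sizes in zip(
        feature_map_shapes(config, image_size), config.strides, config.anchor_sizes
    ):
        cy, cx = np.meshgrid(
            (np.arange(fh) + 0.5) * stride, (np.arange(fw) + 0.5) * stride, indexing="ij"
        )
        for_level = np.empty((fh, fw, len(sizes), 4))
        for k, (aw, ah) in enumerate(sizes):
            for_level[:, :, k, 0] = cx
            for_level[:, :, k, 1] = cy
            for_level[:, :, k, 2] = aw
            for_level[:, :, k, 3] = ah
        rows.append(for_level.reshape(-1, 4))
    return np.concatenate(rows, axis=0)


def _to_corners(cwh: np.ndarray) -> np.ndarray:
    x1 = cwh[:, 0] - cwh[:, 2] / 2
    y1 = cwh[:, 1] - cwh[:, 3] / 2
    return np.stack([x1, y1, x1 + cwh[:, 2], y1 + cwh[:, 3]], axis=1)


def box_xywh_to_cwh(xywh: np.ndarray) -> np.ndarray:
    """(x, y, w, h) corner-origin boxes -> (cx, cy, w, h)."""
    xywh = np.atleast_2d(np.asarray(xywh, dtype=float))
    return np.stack(
        [xywh[:, 0] + xywh[:, 2] / 2, xywh[:, 1] + xywh[:, 3] / 2, xywh[:, 2], xywh[:, 3]], axis=1
    )


def iou_matrix(anchors_cwh: np.ndarray, boxes_cwh: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union, (A, B)."""
    a = _to_corners(np.atleast_2d(anchors_cwh))
    b = _to_corners(np.atleast_2d(boxes_cwh))
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def assign_anchors(
    anchors_cwh: np.ndarray, gt_boxes_cwh: np.ndarray, config: DetectorConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Label every anchor positive / negative / ignore and match it to
    a ground-truth box.

    An anchor is positive when its best IoU reaches the positive
    threshold, negative below the negative threshold, ignored between.
    Additionally each ground truth forces its own argmax anchor
    positive, so no object goes unmatched.  With zero ground-truth
    boxes everything is negative.

    Returns ``(labels, matched_gt_index)``; the match index is -1 for
    non-positive anchors.
    """
    n = len(anchors_cwh)
    labels = np.full(n, NEGATIVE, dtype=int)
    matched = np.full(n, -1, dtype=int)
    gt = np.atleast_2d(np.asarray(gt_boxes_cwh, dtype=float))
    if gt.size == 0:
        return labels, matched
    ious = iou_matrix(anchors_cwh, gt)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]
    labels[best_iou >= config.iou_positive] = POSITIVE
    labels[(best_iou >= config.iou_negative) & (best_iou < config.iou_positive)] = IGNORE
    matched[labels == POSITIVE] = best_gt[labels == POSITIVE]
    # argmax forcing: every ground truth keeps its best anchor
    forced = ious.argmax(axis=0)
    labels[forced] = POSITIVE
    matched[forced] = np.arange(gt.shape[0])
    return labels, matched


def _check_anchors(anchors_cwh: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(np.asarray(anchors_cwh, dtype=float))
    if np.any(a[:, 2] <= 0) or np.any(a[:, 3] <= 0):
        raise ValueError("anchor width/height must be positive")
    return a


def encode_box(anchors_cwh: np.ndarray, boxes_cwh: np.ndarray) -> np.ndarray:
    """Ground-truth boxes -> (tx, ty, tw, th) anchor-relative offsets."""
    a = _check_anchors(anchors_cwh)
    b = np.atleast_2d(np.asarray(boxes_cwh, dtype=float))
    if np.any(b[:, 2] <= 0) or np.any(b[:, 3] <= 0):
        raise ValueError("box width/height must be positive")
    return np.stack(
        [
            (b[:, 0] - a[:, 0]) / a[:, 2],
            (b[:, 1] - a[:, 1]) / a[:, 3],
            np.log(b[:, 2] / a[:, 2]),
            np.log(b[:, 3] / a[:, 3]),
        ],
        axis=1,
    )


def decode_box(anchors_cwh: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(tx, ty, tw, th) offsets -> (cx, cy, w, h) boxes."""
    a = _check_anchors(anchors_cwh)
    t = np.atleast_2d(np.asarray(t, dtype=float))
    return np.stack(
        [
            a[:, 0] + t[:, 0] * a[:, 2],
            a[:, 1] + t[:, 1] * a[:, 3],
            a[:, 2] * np.exp(t[:, 2]),
            a[:, 3] * np.exp(t[:, 3]),
        ],
        axis=1,
    )


def encode_keypoints(anchors_cwh: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Keypoints (A, 6) as (lx1, ly1, lx2, ly2, lx3, ly3) pixel coords ->
    anchor-relative offsets, landmark order preserved."""
    a = _check_anchors(anchors_cwh)
    p = np.atleast_2d(np.asarray(pts, dtype=float)).reshape(len(a), 3, 2)
    out = np.empty_like(p)
    out[:, :, 0] = (p[:, :, 0] - a[:, None, 0]) / a[:, None, 2]
    out[:, :, 1] = (p[:, :, 1] - a[:, None, 1]) / a[:, None, 3]
    return out.reshape(len(a), 6)


def decode_keypoints(anchors_cwh: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Anchor-relative keypoint offsets -> pixel coordinates (A, 6)."""
    a = _check_anchors(anchors_cwh)
    off = np.atleast_2d(np.asarray(l, dtype=float)).reshape(len(a), 3, 2)
    out = np.empty_like(off)
    out[:, :, 0] = a[:, None, 0] + off[:, :, 0] * a[:, None, 2]
    out[:, :, 1] = a[:, None, 1] + off[:, :, 1] * a[:, None, 3]
    return out.reshape(len(a), 6)


def nms(boxes_cwh: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores)
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes_cwh[i : i + 1], boxes_cwh[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.asarray(keep, dtype=int)
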