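"""Inference: detections with boxes, confidences and keypoints.

The image is mean-subtracted, edge-padded to a stride multiple, and run
through the network.  Foreground softmax scores are thresholded, boxes
decoded and NMS-suppressed, and the best (at most two) detections kept.
Laterality is assigned by image position: in a frontal, un-mirrored
photograph the patient's right eye is the leftmost detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from ..scoring import Laterality, OcularKeyPoints
from .anchors import decode_box, decode_keypoints, generate_anchors, nms
from .model import INPUT_SCALE, EyeDetector


@dataclass(frozen=True)
class EyeDetection:
    """One detected eye: pixel box (x, y, w, h), landmarks, confidence."""

    box: tuple
    keypoints: OcularKeyPoints
    confidence: float
    laterality: Laterality


def _softmax_fg(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def predict(model: EyeDetector, image: np.ndarray) -> List[EyeDetection]:
    """Detect up to two eyes with their three keypoints each.

    Returns an empty list when nothing clears the score threshold (the
    caller reports such an image as unscorable).
    """
    cfg = model.config
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape
    top = max(cfg.strides)
    ph, pw = (-h) % top, (-w) % top
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    x = ((img - model.input_mean) * INPUT_SCALE)[None, None, :, :]
    cls_out, box_out, pts_out = model.forward(x)
    model.clear_caches()
    anchors = generate_anchors(cfg, img.shape)
    scores = _softmax_fg(cls_out[0])
    keep = scores >= cfg.score_threshold
    if not keep.any():
        return []
    idx = np.flatnonzero(keep)
    boxes = decode_box(anchors[idx], box_out[0][idx])
    pts = decode_keypoints(anchors[idx], pts_out[0][idx])
    kept = nms(boxes, scores[idx], cfg.nms_iou)[: cfg.max_detections]
    if cfg.cluster_voting:
        from .anchors import iou_matrix

        boxes_v = boxes.copy()
        pts_v = pts.copy()
        for k in kept:
            member = iou_matrix(boxes[k : k + 1], boxes)[0] > cfg.nms_iou
            wgt = scores[idx][member]
            boxes_v[k] = wgt @ boxes[member] / wgt.sum()
            pts_v[k] = wgt @ pts[member] / wgt.sum()
        boxes, pts = boxes_v, pts_v
    order = kept[np.argsort([boxes[k, 0] for k in kept])]  # left-to-right in image
    detections: List[EyeDetection] = []
    for rank, k in enumerate(order):
        cx, cy, bw, bh = boxes[k]
        x1 = float(np.clip(cx - bw / 2, 0, w - 1))
        y1 = float(np.clip(cy - bh / 2, 0, h - 1))
        x2 = float(np.clip(cx + bw / 2, 0, w - 1))
        y2 = float(np.clip(cy + bh / 2, 0, h - 1))
        if len(order) == 2:
            lat: Laterality = "right" if rank == 0 else "left"
        else:
            lat = "right" if cx < w / 2 else "left"
        p = np.clip(pts[k].reshape(3, 2), 0, [w - 1, h - 1])
        kp = OcularKeyPoints(
            lateral_canthus=(float(p[0, 0]), float(p[0, 1])),
            pupil_center=(float(p[1, 0]), float(p[1, 1])),
            medial_canthus=(float(p[2, 0]), float(p[2, 1])),
            eye=lat,
        )
        detections.append(
            EyeDetection(
                box=(x1, y1, x2 - x1, y2 - y1),
                keypoints=kp,
                confidence=float(scores[idx[k]]),
                laterality=lat,
            )
        )
    return detections
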