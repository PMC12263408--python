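"""Anchor-wise multi-task detection loss.

For every anchor *i* the training loss combines a two-class softmax
classification term with box and keypoint regression terms that are
switched on only for positive (object-containing) anchors:

    L_total = L_cls(p_i, p_i*) + lambda1 p_i* L_box(t_i, t_i*)
                                + lambda2 p_i* L_pts(l_i, l_i*)

Negative anchors contribute only classification; ignore-labelled
anchors contribute nothing.  Both regression terms use the smooth-L1
(Huber) loss on anchor-relative offsets.  Each head is averaged over
its contributing anchors (classification over all non-ignored anchors,
regression over positive anchors and their coordinates), so the three
reported components satisfy ``total = cls + lambda1*box + lambda2*pts``
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .anchors import IGNORE, POSITIVE
from .config import LossWeights


@dataclass
class LossOutput:
    total: float
    cls: float
    box: float
    pts: float
    # gradients w.r.t. the raw predictions (same shapes), or None
    d_logits: Optional[np.ndarray] = None
    d_box: Optional[np.ndarray] = None
    d_pts: Optional[np.ndarray] = None


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _smooth_l1(d: np.ndarray, beta: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise smooth-L1 value and derivative.

    ``beta`` is the quadratic/linear transition point; below it the loss
    is 0.5 d^2 / beta, above it |d| - beta/2.
    """
    ad = np.abs(d)
    val = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    grad = np.clip(d / beta, -1.0, 1.0)
    return val, grad


def multi_task_loss(
    cls_logits: np.ndarray,
    box_pred: np.ndarray,
    pts_pred: np.ndarray,
    labels: np.ndarray,
    box_targets: np.ndarray,
    pts_targets: np.ndarray,
    weights: LossWeights,
    with_grads: bool = False,
    beta: float = 1.0,
) -> LossOutput:
    """Loss over one batch of anchors.

    ``cls_logits`` is (A, 2) with column 1 the foreground class;
    ``labels`` is (A,) in {1 positive, 0 negative, -1 ignore};
    regression predictions/targets are (A, 4) and (A, 6) and are read
    only at positive rows.  With no positive anchor, the regression
    components are zero by convention.
    """
    labels = np.asarray(labels)
    valid = labels != IGNORE
    pos = labels == POSITIVE
    n_valid = int(valid.sum())
    n_pos = int(pos.sum())
    if n_valid == 0:
        raise ValueError("all anchors are ignore-labelled; nothing to train on")

    probs = _softmax(cls_logits)
    eps = 1e-12
    target_col = np.where(labels == POSITIVE, 1, 0)
    picked = probs[np.arange(len(labels)), target_col]
    cls = float(-np.log(np.clip(picked[valid], eps, None)).mean())

    if n_pos:
        box_val, box_grad = _smooth_l1(box_pred[pos] - box_targets[pos], beta)
        pts_val, pts_grad = _smooth_l1(pts_pred[pos] - pts_targets[pos], beta)
        box = float(box_val.mean())
        pts = float(pts_val.mean())
    else:
        box = pts = 0.0
    total = cls + weights.lambda1 * box + weights.lambda2 * pts
    out = LossOutput(total=total, cls=cls, box=box, pts=pts)

    if with_grads:
        d_logits = np.zeros_like(cls_logits)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(labels)), target_col] = 1.0
        d_logits[valid] = (probs[valid] - onehot[valid]) / n_valid
        d_box = np.zeros_like(box_pred)
        d_pts = np.zeros_like(pts_pred)
        if n_pos:
            d_box[pos] = weights.lambda1 * box_grad / (n_pos * box_pred.shape[1])
            d_pts[pos] = weights.lambda2 * pts_grad / (n_pos * pts_pred.shape[1])
        out.d_logits, out.d_box, out.d_pts = d_logits, d_box, d_pts
    return out
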