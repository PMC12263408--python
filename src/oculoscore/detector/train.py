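"""SGD training loop for the eye detector.

Images are augmented per epoch, mean-subtracted with the training-set
gray mean, and batched; every anchor is labelled against the image's
ground-truth eye boxes, the positive anchors are given box/keypoint
regression targets, and the multi-task loss is backpropagated through
the network.  The learning rate follows the configured warm-up/decay
schedule; a new rate takes effect at the start of the epoch after each
breakpoint.  With a fixed seed the whole run (data order, augmentation
draws, weight init) is deterministic.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..augment import apply_augmentation
from ..io import AnnotatedImage
from ..nn import SGDMomentum
from .anchors import (
    POSITIVE,
    assign_anchors,
    box_xywh_to_cwh,
    encode_box,
    encode_keypoints,
    generate_anchors,
)
from .config import DetectorConfig
from .loss import multi_task_loss
from .model import INPUT_SCALE, EyeDetector


def build_targets(
    anchors: np.ndarray, ann: AnnotatedImage, config: DetectorConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-anchor labels and encoded box/keypoint targets for one image."""
    eyes = [ann.eyes[lat] for lat in sorted(ann.eyes)]
    gt_boxes = box_xywh_to_cwh([e.box for e in eyes]) if eyes else np.zeros((0, 4))
    labels, matched = assign_anchors(anchors, gt_boxes, config)
    box_t = np.zeros((len(anchors), 4))
    pts_t = np.zeros((len(anchors), 6))
    pos = labels == POSITIVE
    if pos.any():
        idx = matched[pos]
        box_t[pos] = encode_box(anchors[pos], gt_boxes[idx])
        pts = np.array([eyes[i].keypoints.as_tuple() for i in idx])
        pts_t[pos] = encode_keypoints(anchors[pos], pts)
    return labels, box_t, pts_t


def dataset_mean(images: Sequence[AnnotatedImage]) -> float:
    """Training-set gray-level mean (computed once, stored in the model)."""
    return float(np.mean([ann.image.mean() for ann in images]))


def train(
    dataset: Sequence[AnnotatedImage],
    config: Optional[DetectorConfig] = None,
    seed: int = 0,
    verbose: bool = False,
) -> Tuple[EyeDetector, pd.DataFrame]:
    """Train a detector; returns the model and the per-epoch loss log.

    The log has one row per epoch with columns
    ``epoch, lr, cls, box, pts, total`` (means over the epoch's steps).
    """
    if not len(dataset):
        raise ValueError("training dataset is empty")
    config = config or DetectorConfig()
    ss = np.random.SeedSequence(seed)
    init_seed, order_seed, aug_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    model = EyeDetector(config, seed=init_seed)
    model.input_mean = dataset_mean(dataset)
    anchors = generate_anchors(config, config.input_size)
    optimizer = SGDMomentum(model.params(), momentum=config.momentum, weight_decay=config.weight_decay)
    order_rng = np.random.default_rng(order_seed)
    aug_rng = np.random.default_rng(aug_seed)
    th, tw = config.input_size
    log_rows = []
    for epoch in range(1, config.schedule.total_epochs + 1):
        lr = config.schedule.lr_at(epoch)
        order = order_rng.permutation(len(dataset))
        sums = np.zeros(4)
        n_steps = 0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            tensors, labels_l, box_l, pts_l = [], [], [], []
            for i in batch_idx:
                aug = apply_augmentation(dataset[i], config.augmentation, aug_rng)
                img = aug.image
                if img.shape != (th, tw):
                    raise ValueError(
                        f"augmented image {img.shape} does not match the input size {(th, tw)}"
                    )
                tensors.append((img - model.input_mean) * INPUT_SCALE)
                lab, bt, pt = build_targets(anchors, aug, config)
                labels_l.append(lab)
                box_l.append(bt)
                pts_l.append(pt)
            x = np.stack(tensors)[:, None, :, :]
            cls_out, box_out, pts_out = model.forward(x)
            n = len(batch_idx)
            a = len(anchors)
            out = multi_task_loss(
                cls_out.reshape(n * a, 2),
                box_out.reshape(n * a, 4),
                pts_out.reshape(n * a, 6),
                np.concatenate(labels_l),
                np.concatenate(box_l),
                np.concatenate(pts_l),
                config.loss_weights,
                with_grads=True,
                beta=config.smooth_l1_beta,
            )
            optimizer.zero_grad()
            model.backward(
                out.d_logits.reshape(n, a, 2),
                out.d_box.reshape(n, a, 4),
                out.d_pts.reshape(n, a, 6),
            )
            optimizer.step(lr)
            sums += (out.cls, out.box, out.pts, out.total)
            n_steps += 1
        means = sums / max(n_steps, 1)
        log_rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "cls": means[0],
                "box": means[1],
                "pts": means[2],
                "total": means[3],
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {lr:.0e}  cls {means[0]:.4f}  "
                f"box {means[1]:.4f}  pts {means[2]:.4f}  total {means[3]:.4f}"
            )
    return model, pd.DataFrame(log_rows)
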