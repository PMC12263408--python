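"""Single-stage anchor-based eye detector network.

A small convolutional backbone (stride-2 stages) feeds a three-level
feature pyramid (lateral 1x1 projections plus nearest-neighbour
top-down fusion).  Each pyramid level passes through its own context
module — three parallel stacks of 3x3 convolutions with receptive
fields 3, 5 and 7, channel-concatenated — before three 1x1 heads,
shared across levels, emit per-anchor foreground logits, box offsets
and the six keypoint offsets.

Everything is plain NumPy with hand-written backprop (see
``oculoscore.nn``); forward and backward walk the same explicit graph.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from ..nn import Conv2d, Param, ReLU, Upsample2x
from .anchors import feature_map_shapes, generate_anchors
from .config import DetectorConfig, LossWeights, TrainSchedule

CHECKPOINT_MAGIC = "oculoscore-detector-v1"

#: Fixed input scaling applied after mean subtraction, so gray levels
#: enter the network at roughly unit amplitude.
INPUT_SCALE = 1.0 / 128.0


def _seq_forward(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def _seq_backward(layers, d):
    for layer in reversed(layers):
        d = layer.backward(d)
    return d


class ContextModule:
    """Parallel 3x3-conv branches (receptive fields 3/5/7), concatenated."""

    def __init__(self, width: int, rng: np.random.Generator):
        if width % 4:
            raise ValueError("context module width must be divisible by 4")
        w2, w4 = width // 2, width // 4
        self.branches = [
            [Conv2d(width, w2, 3, rng=rng)],
            [Conv2d(width, w4, 3, rng=rng), ReLU(), Conv2d(w4, w4, 3, rng=rng)],
            [
                Conv2d(width, w4, 3, rng=rng),
                ReLU(),
                Conv2d(w4, w4, 3, rng=rng),
                ReLU(),
                Conv2d(w4, w4, 3, rng=rng),
            ],
        ]
        self.relu = ReLU()
        self._splits = (w2, w2 + w4)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.concatenate([_seq_forward(b, x) for b in self.branches], axis=1)
        return self.relu.forward(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        parts = np.split(d, self._splits, axis=1)
        dx = None
        for branch, dpart in zip(self.branches, parts):
            g = _seq_backward(branch, np.ascontiguousarray(dpart))
            dx = g if dx is None else dx + g
        return dx

    def params(self) -> List[Param]:
        out = []
        for b in self.branches:
            for layer in b:
                out.extend(layer.params())
        return out

    def layers(self):
        for b in self.branches:
            yield from b
        yield self.relu


class EyeDetector:
    """The detector network plus its anchors and preprocessing state."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.input_mean = 0.0  # training-set gray mean, set by the trainer
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        widths = config.backbone_widths
        cin = config.in_channels
        self.stages = []
        for w in widths:
            self.stages.append(
                [Conv2d(cin, w, 3, stride=2, rng=rng), ReLU(), Conv2d(w, w, 3, rng=rng), ReLU()]
            )
            cin = w
        if len(widths) < 3:
            raise ValueError("backbone needs at least 3 stages")
        fw = config.fpn_width
        self.laterals = [Conv2d(widths[i], fw, 1, rng=rng) for i in (-3, -2, -1)]
        self.upsamples = [Upsample2x(), Upsample2x()]
        self.contexts = [ContextModule(fw, rng) for _ in config.strides]
        a = self.config.anchors_per_cell
        tw = config.head_tower_width
        self.tower = [Conv2d(fw, tw, 3, rng=rng), ReLU()] if tw else []
        head_in = tw or fw
        self.head_cls = Conv2d(head_in, a * 2, 1, rng=rng)
        self.head_box = Conv2d(head_in, a * 4, 1, rng=rng)
        self.head_pts = Conv2d(head_in, a * 6, 1, rng=rng)
        # background-leaning classification prior stabilizes early training
        self.head_cls.b.value[1::2] = -2.0
        self._fwd_shapes: Optional[list] = None

    # ---- parameter plumbing -------------------------------------------------
    def params(self) -> List[Param]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def _all_layers(self):
        for stage in self.stages:
            yield from stage
        yield from self.laterals
        yield from self.upsamples
        for ctx in self.contexts:
            yield from ctx.layers()
        yield from self.tower
        yield self.head_cls
        yield self.head_box
        yield self.head_pts

    def clear_caches(self) -> None:
        for layer in self._all_layers():
            if hasattr(layer, "_cache"):
                layer._cache = []

    # ---- forward / backward -------------------------------------------------
    def build_feature_pyramid(self, x: np.ndarray) -> List[np.ndarray]:
        """Backbone + FPN + context modules; one map per pyramid level.

        ``x`` is (N, C, H, W) with H, W divisible by the largest stride.
        """
        top = max(self.config.strides)
        if x.shape[2] % top or x.shape[3] % top:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} must be divisible by the largest stride {top}"
            )
        h = x
        feats = []
        n_stages = len(self.stages)
        for i, stage in enumerate(self.stages):
            h = _seq_forward(stage, h)
            if i >= n_stages - 3:
                feats.append(h)
        c3, c4, c5 = feats
        l3 = self.laterals[0].forward(c3)
        l4 = self.laterals[1].forward(c4)
        l5 = self.laterals[2].forward(c5)
        p5 = l5
        p4 = l4 + self.upsamples[1].forward(p5)
        p3 = l3 + self.upsamples[0].forward(p4)
        return [ctx.forward(p) for ctx, p in zip(self.contexts, (p3, p4, p5))]

    def _head_reshape(self, y: np.ndarray, c: int) -> np.ndarray:
        """(N, A_cell*c, fh, fw) head map -> (N, fh*fw*A_cell, c) rows in
        anchor order (row-major cells, then anchor size)."""
        n, _, fh, fw = y.shape
        a = self.config.anchors_per_cell
        return (
            y.reshape(n, a, c, fh, fw).transpose(0, 3, 4, 1, 2).reshape(n, fh * fw * a, c)
        )

    def _head_unreshape(self, d: np.ndarray, c: int, fh: int, fw: int) -> np.ndarray:
        n = d.shape[0]
        a = self.config.anchors_per_cell
        return np.ascontiguousarray(
            d.reshape(n, fh, fw, a, c).transpose(0, 3, 4, 1, 2).reshape(n, a * c, fh, fw)
        )

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run the network; returns per-anchor (cls logits, box, pts).

        Shapes: (N, A, 2), (N, A, 4), (N, A, 6) with anchors in the
        deterministic order of :func:`generate_anchors`.
        """
        pyramids = self.build_feature_pyramid(x)
        self._fwd_shapes = [p.shape for p in pyramids]
        cls_rows, box_rows, pts_rows = [], [], []
        for p in pyramids:
            t = _seq_forward(self.tower, p) if self.tower else p
            cls_rows.append(self._head_reshape(self.head_cls.forward(t), 2))
            box_rows.append(self._head_reshape(self.head_box.forward(t), 4))
            pts_rows.append(self._head_reshape(self.head_pts.forward(t), 6))
        return (
            np.concatenate(cls_rows, axis=1),
            np.concatenate(box_rows, axis=1),
            np.concatenate(pts_rows, axis=1),
        )

    def backward(self, d_cls: np.ndarray, d_box: np.ndarray, d_pts: np.ndarray) -> None:
        """Accumulate parameter gradients from per-anchor output grads."""
        if self._fwd_shapes is None:
            raise RuntimeError("backward called before forward")
        shapes = self._fwd_shapes
        a = self.config.anchors_per_cell
        counts = [s[2] * s[3] * a for s in shapes]
        edges = np.cumsum(counts)[:-1]
        cls_parts = np.split(d_cls, edges, axis=1)
        box_parts = np.split(d_box, edges, axis=1)
        pts_parts = np.split(d_pts, edges, axis=1)
        # heads were applied per level in forward order; pop caches in reverse
        d_ctx_out = [None, None, None]
        for lvl in (2, 1, 0):
            _, _, fh, fw = shapes[lvl]
            d = self.head_pts.backward(self._head_unreshape(pts_parts[lvl], 6, fh, fw))
            d = d + self.head_box.backward(self._head_unreshape(box_parts[lvl], 4, fh, fw))
            d = d + self.head_cls.backward(self._head_unreshape(cls_parts[lvl], 2, fh, fw))
            if self.tower:
                d = _seq_backward(self.tower, d)
            d_ctx_out[lvl] = d
        dp3 = self.contexts[0].backward(d_ctx_out[0])
        dp4 = self.contexts[1].backward(d_ctx_out[1]) + self.upsamples[0].backward(dp3)
        dp5 = self.contexts[2].backward(d_ctx_out[2]) + self.upsamples[1].backward(dp4)
        dc3 = self.laterals[0].backward(dp3)
        dc4 = self.laterals[1].backward(dp4)
        dc5 = self.laterals[2].backward(dp5)
        d = _seq_backward(self.stages[-1], dc5)
        d = _seq_backward(self.stages[-2], d + dc4)
        d = _seq_backward(self.stages[-3], d + dc3)
        for stage in reversed(self.stages[:-3]):
            d = _seq_backward(stage, d)
        self._fwd_shapes = None

    # ---- anchors ------------------------------------------------------------
    def anchors(self, image_size: Optional[Tuple[int, int]] = None) -> np.ndarray:
        return generate_anchors(self.config, image_size or self.config.input_size)

    # ---- checkpointing ------------------------------------------------------
    def save(self, path: Path) -> None:
        """Write weights + config + seed as a versioned .npz checkpoint."""
        from dataclasses import asdict

        header = json.dumps(
            {
                "magic": CHECKPOINT_MAGIC,
                "seed": self.seed,
                "input_mean": self.input_mean,
                "config": asdict(self.config),
            }
        )
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: Path) -> "EyeDetector":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header.get("magic") != CHECKPOINT_MAGIC:
                raise ValueError(f"{path}: not a detector checkpoint (bad header)")
            cfg_dict = header["config"]
            from ..augment import AugmentationConfig

            cfg_dict["loss_weights"] = LossWeights(**cfg_dict["loss_weights"])
            cfg_dict["schedule"] = TrainSchedule(
                **{**cfg_dict["schedule"], "decay_epochs": tuple(cfg_dict["schedule"]["decay_epochs"])}
            )
            aug = cfg_dict["augmentation"]
            for key in ("crop_fraction", "brightness_range"):
                aug[key] = tuple(aug[key])
            if aug.get("target_size") is not None:
                aug["target_size"] = tuple(aug["target_size"])
            cfg_dict["augmentation"] = AugmentationConfig(**aug)
            for key in ("input_size", "backbone_widths", "strides"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg_dict["anchor_sizes"] = tuple(
                tuple(tuple(sz) for sz in level) for level in cfg_dict["anchor_sizes"]
            )
            config = DetectorConfig(**cfg_dict)
            model = cls(config, seed=header["seed"])
            model.input_mean = header["input_mean"]
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
        return model
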