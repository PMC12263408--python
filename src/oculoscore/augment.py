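"""Keypoint-consistent training-time augmentation.

The pipeline applies, in order: random cropping, aspect-ratio padding,
bounded random rotation (with a retry rule), random brightness, scaling
to the model input size, and mean subtraction.  Every geometric step
transforms boxes and keypoints with the *same* affine map applied to
the pixels, so landmark annotations stay glued to the anatomy.

Rotation may push a landmark out of the frame.  In that case the random
angle is redrawn, up to a configurable number of retries (default 3);
if the last draw still loses a landmark, the rotation step is skipped
and the un-rotated image is used.  An accepted rotation therefore
always keeps every keypoint of every annotated eye strictly inside the
image bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io import AnnotatedImage, Box, EyeAnnotation
from .scoring import OcularKeyPoints


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the augmentation pipeline.

    ``crop_fraction`` is the linear size of the random crop relative to
    the image; ``target_size`` the (H, W) the image is scaled to at the
    end; ``mean`` the training-set gray-level mean subtracted last
    (computed once over the training set, not per image).
    """

    crop_fraction: Tuple[float, float] = (0.9, 1.0)
    target_size: Optional[Tuple[int, int]] = None  # None: keep size
    max_rotation_deg: float = 40.0
    max_rotation_retries: int = 3
    brightness_range: Tuple[float, float] = (0.8, 1.2)
    mean: float = 0.0
    p_crop: float = 1.0
    p_rotate: float = 0.5
    p_brightness: float = 1.0
    crop_attempts: int = 3  # redraws of a crop window that cuts an eye

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0 or self.max_rotation_retries < 0:
            raise ValueError("rotation bounds must be non-negative")
        if not 0 < self.crop_fraction[0] <= self.crop_fraction[1] <= 1:
            raise ValueError("crop_fraction must satisfy 0 < lo <= hi <= 1")


def _transform_eyes(ann: AnnotatedImage, fn) -> Dict:
    """Apply a point map (x, y) -> (x', y') to all boxes and keypoints."""
    out = {}
    for lat, eye in ann.eyes.items():
        kp = eye.keypoints
        pts = {name: fn(*getattr(kp, name)) for name in ("lateral_canthus", "pupil_center", "medial_canthus")}
        x, y, w, h = eye.box
        corners = [fn(x, y), fn(x + w, y), fn(x, y + h), fn(x + w, y + h)]
        xs = [c[0] for c in corners]
        ys = [c[1] for c in corners]
        box: Box = (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
        out[lat] = EyeAnnotation(box=box, keypoints=OcularKeyPoints(eye=lat, **pts))
    return out


def _keypoints_in_bounds(eyes: Dict, shape: Tuple[int, int]) -> bool:
    h, w = shape
    for eye in eyes.values():
        for name in ("lateral_canthus", "pupil_center", "medial_canthus"):
            x, y = getattr(eye.keypoints, name)
            if not (0 < x < w - 1 and 0 < y < h - 1):
                return False
    return True


def rotate_annotated(ann: AnnotatedImage, angle_deg: float) -> AnnotatedImage:
    """Rotate image and annotations about the image center.

    A single rotation matrix defines both the pixel resampling (bilinear,
    edge-replicated border) and the landmark map, so the two cannot
    drift apart.  Positive angles rotate content counter-clockwise in
    the usual mathematical sense of the (x, right; y, down) pixel frame.
    """
    h, w = ann.shape
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    # output pixel o samples input at rot^-1 (o - c) + c;  ndimage works in
    # (row, col) = (y, x) order, so conjugate the matrix by the axis swap.
    inv = rot.T
    inv_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    center_rc = center[::-1]
    offset = center_rc - inv_rc @ center_rc
    image = ndimage.affine_transform(
        ann.image, inv_rc, offset=offset, order=1, mode="nearest", output=np.float64
    )

    def fwd(x: float, y: float) -> Tuple[float, float]:
        p = rot @ (np.array([x, y]) - center) + center
        return float(p[0]), float(p[1])

    eyes = _transform_eyes(ann, fwd)
    return replace_annotation(ann, image=image, eyes=eyes)


def replace_annotation(ann: AnnotatedImage, image=None, eyes=None) -> AnnotatedImage:
    return AnnotatedImage(
        image_id=ann.image_id,
        image=ann.image if image is None else image,
        gaze=ann.gaze,
        eyes=ann.eyes if eyes is None else eyes,
        provenance=ann.provenance,
    )


def rotate_with_retry(
    ann: AnnotatedImage,
    max_degrees: float,
    max_retries: int,
    rng: np.random.Generator,
) -> Tuple[AnnotatedImage, int, bool]:
    """Random bounded rotation with redraw-on-landmark-loss.

    Draws an angle uniformly in [-max_degrees, +max_degrees]; if any
    keypoint of any annotated eye leaves the image, redraws up to
    ``max_retries`` more times.  If the final draw still loses a
    keypoint the input is returned un-rotated with ``skipped=True``.
    Returns ``(result, attempts_used, skipped)``.
    """
    attempts = 0
    for _ in range(max_retries + 1):
        attempts += 1
        angle = float(rng.uniform(-max_degrees, max_degrees))
        rotated = rotate_annotated(ann, angle)
        if _keypoints_in_bounds(rotated.eyes, rotated.shape):
            return rotated, attempts, False
    return ann, attempts, True


def random_crop(
    ann: AnnotatedImage, cfg: AugmentationConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Random crop keeping every annotated eye; falls back to no crop.

    The crop window is redrawn up to ``cfg.crop_attempts`` times if it
    cuts off any keypoint; annotations are never silently corrupted.
    """
    h, w = ann.shape
    for _ in range(cfg.crop_attempts):
        frac = rng.uniform(*cfg.crop_fraction)
        ch, cw = max(1, int(round(h * frac))), max(1, int(round(w * frac)))
        oy = int(rng.integers(0, h - ch + 1))
        ox = int(rng.integers(0, w - cw + 1))
        eyes = _transform_eyes(ann, lambda x, y: (x - ox, y - oy))
        if _keypoints_in_bounds(eyes, (ch, cw)):
            image = ann.image[oy : oy + ch, ox : ox + cw]
            return replace_annotation(ann, image=image, eyes=eyes)
    return ann


def pad_to_aspect(ann: AnnotatedImage, aspect: float) -> AnnotatedImage:
    """Edge-replicate pad right/bottom until width/height >= ``aspect``."""
    h, w = ann.shape
    if w / h < aspect:
        new_w = int(np.ceil(h * aspect))
        image = np.pad(ann.image, ((0, 0), (0, new_w - w)), mode="edge")
    else:
        new_h = int(np.ceil(w / aspect))
        image = np.pad(ann.image, ((0, new_h - h), (0, 0)), mode="edge")
    return replace_annotation(ann, image=image)


def scale_to(ann: AnnotatedImage, target: Tuple[int, int]) -> AnnotatedImage:
    """Resize to (H, W), scaling annotations by the same factors."""
    h, w = ann.shape
    th, tw = target
    if (th, tw) == (h, w):
        return ann
    sy, sx = th / h, tw / w
    image = ndimage.zoom(ann.image, (sy, sx), order=1, mode="nearest", grid_mode=True)
    eyes = _transform_eyes(ann, lambda x, y: (x * sx, y * sy))
    return replace_annotation(ann, image=image, eyes=eyes)


def apply_augmentation(
    ann: AnnotatedImage, cfg: AugmentationConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Full pipeline: crop, pad, rotate (retry rule), brightness, scale,
    mean subtraction.  Returns a new AnnotatedImage; the input is not
    modified."""
    out = ann
    if cfg.p_crop > 0 and cfg.crop_fraction[0] < 1.0 and rng.uniform() < cfg.p_crop:
        out = random_crop(out, cfg, rng)
    target = cfg.target_size or ann.shape
    out = pad_to_aspect(out, target[1] / target[0])
    if cfg.max_rotation_deg > 0 and rng.uniform() < cfg.p_rotate:
        out, _, _ = rotate_with_retry(out, cfg.max_rotation_deg, cfg.max_rotation_retries, rng)
    if rng.uniform() < cfg.p_brightness:
        factor = rng.uniform(*cfg.brightness_range)
        out = replace_annotation(out, image=np.clip(out.image * factor, 0.0, 255.0))
    out = scale_to(out, target)
    if cfg.mean != 0.0:
        out = replace_annotation(out, image=out.image - cfg.mean)
    return out
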