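"""Synthetic lateral-gaze eye photographs with exact ground truth.

Each generated canvas emulates a frontal binocular photograph taken
while the subject gazes maximally left or right: two almond-shaped
palpebral fissures (elliptical lid arcs meeting at the canthi, outlined
by a dark lid line) on a skin-toned background, each containing a dark
iris/pupil disc whose horizontal position encodes a *planted* canthal
ratio — and therefore a known severity score.  Additive Gaussian noise
and a global brightness factor make detection non-trivial; an optional
epicanthal fold occludes the medial corner photometrically without
moving the geometric ground truth.

Because the landmarks are returned exactly where they are drawn, the
closed loop (render -> score the ground-truth keypoints) reproduces the
planted score for every image: planted ratios keep a 0.02 margin from
the quartile bucket edges so no floating-point wobble can flip a bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import AnnotatedImage, Box, EyeAnnotation, save_image, write_csv, write_labelme
from .scoring import GazeDirection, Laterality, OcularKeyPoints, movement_roles, score_from_ratio

#: Planted ratios stay this far inside their score bucket.
BUCKET_MARGIN = 0.02

#: Sampling interval of the planted ratio for each score bucket.
SCORE_RATIO_RANGES: Dict[int, Tuple[float, float]] = {
    1: (BUCKET_MARGIN, 0.25 - BUCKET_MARGIN),
    2: (0.25 + BUCKET_MARGIN, 0.50 - BUCKET_MARGIN),
    3: (0.50 + BUCKET_MARGIN, 0.75 - BUCKET_MARGIN),
    4: (0.75 + BUCKET_MARGIN, 1.0 - BUCKET_MARGIN),
}


@dataclass(frozen=True)
class SyntheticSubjectParams:
    """Geometry and photometry of one rendered subject.

    Lengths are pixels, intensities 8-bit gray levels.  Defaults are
    sized for a 256x128 canvas at roughly the scale of a cropped
    periocular photograph: canthal width ~60 px, interocular distance
    ~110 px, pupil radius 8 px.
    """

    image_size: Tuple[int, int] = (128, 256)  # (H, W)
    interocular: float = 110.0
    canthal_width: float = 62.0
    fissure_height: float = 30.0
    canthal_tilt: float = 2.0  # lateral-canthus y offset vs medial (px)
    pupil_radius: float = 8.0
    iris_intensity: float = 40.0
    sclera_intensity: float = 235.0
    skin_intensity: float = 180.0
    lid_intensity: float = 90.0
    caruncle_radius: float = 3.5  # medial-corner caruncle (px)
    caruncle_intensity: float = 150.0
    epicanthus: bool = False
    epicanthus_depth: float = 0.15  # fraction of canthal width occluded
    noise_sigma: float = 3.0
    brightness_jitter: float = 0.15

    def __post_init__(self) -> None:
        if self.canthal_width <= 2 * self.pupil_radius:
            raise ValueError("canthal width must exceed the pupil diameter")
        h, w = self.image_size
        if self.interocular + self.canthal_width + 8 > w or self.fissure_height + 8 > h:
            raise ValueError("eye geometry does not fit the canvas")


@dataclass(frozen=True)
class PlantedSeverity:
    """Ground-truth severity planted into one rendered photograph."""

    gaze: Laterality
    abduction_score: Optional[int] = None
    adduction_score: Optional[int] = None
    abduction_ratio: Optional[float] = None
    adduction_ratio: Optional[float] = None

    def resolve_ratio(self, movement: str, rng: np.random.Generator) -> float:
        """Exact planted ratio for a movement, sampling inside the score
        bucket (margin kept from both edges) when only a score is given."""
        ratio = self.abduction_ratio if movement == "abduction" else self.adduction_ratio
        if ratio is not None:
            if not 0.0 <= ratio <= 1.0:
                raise ValueError(f"target ratio {ratio} outside [0, 1]")
            return float(ratio)
        score = self.abduction_score if movement == "abduction" else self.adduction_score
        if score is None:
            raise ValueError(f"planted severity gives neither score nor ratio for {movement}")
        lo, hi = SCORE_RATIO_RANGES[score]
        return float(rng.uniform(lo, hi))


def _eye_centers(params: SyntheticSubjectParams) -> Dict[Laterality, float]:
    """Image-x of each eye center; the patient's right eye is leftmost."""
    _, w = params.image_size
    return {"right": w / 2.0 - params.interocular / 2.0, "left": w / 2.0 + params.interocular / 2.0}


def render_eye(
    params: SyntheticSubjectParams,
    pupil_ratio: float,
    eye: Laterality,
    gaze: Laterality,
    rng: np.random.Generator,
    center: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, OcularKeyPoints, Box]:
    """Render one eye onto a fresh canvas-sized layer.

    Returns the layer (NaN outside the painted eye region, so layers
    composite onto a background), the ground-truth keypoints, and the
    eye bounding box.  ``pupil_ratio`` is the planted canthal ratio of
    the movement this eye performs under ``gaze``.
    """
    h, w = params.image_size
    if center is None:
        center = (_eye_centers(params)[eye], h / 2.0)
    cx, cy = center
    half = params.canthal_width / 2.0
    # Anatomical sides on the image axis: the patient's right eye has its
    # lateral (temporal) canthus on the image-left side.
    lateral_sign = -1.0 if eye == "right" else 1.0
    x_lat = cx + lateral_sign * half
    x_med = cx - lateral_sign * half
    tilt = params.canthal_tilt + rng.uniform(-1.0, 1.0)
    y_lat = cy - tilt / 2.0
    y_med = cy + tilt / 2.0

    movement = movement_roles(gaze)[eye]
    x_target, x_other = (x_lat, x_med) if movement == "abduction" else (x_med, x_lat)
    y_target, y_other = (y_lat, y_med) if movement == "abduction" else (y_med, y_lat)
    if not 0.0 <= pupil_ratio <= 1.0:
        raise ValueError(f"pupil ratio {pupil_ratio} outside the renderable range [0, 1]")
    px = x_target + pupil_ratio * (x_other - x_target)
    py = y_target + pupil_ratio * (y_other - y_target)

    xs = np.arange(w)[None, :]
    ys = np.arange(h)[:, None]
    x_img_left, x_img_right = min(x_lat, x_med), max(x_lat, x_med)
    y_img_left = y_lat if x_lat < x_med else y_med
    y_img_right = y_med if x_lat < x_med else y_lat
    u = np.clip((xs - x_img_left) / (x_img_right - x_img_left), 0.0, 1.0)
    centerline = y_img_left + u * (y_img_right - y_img_left)
    half_height = (params.fissure_height / 2.0) * np.sqrt(np.maximum(0.0, 1.0 - (2.0 * u - 1.0) ** 2))
    inside_x = (xs >= x_img_left) & (xs <= x_img_right)
    dist = np.abs(ys - centerline)
    fissure = inside_x & (dist <= half_height)
    lid_line = inside_x & (dist > half_height) & (dist <= half_height + 1.5) & (half_height > 0)

    layer = np.full((h, w), np.nan)
    # caruncle: the fleshy medial-corner body real photographs show; it is
    # also the only local cue distinguishing the medial from the lateral
    # corner of an otherwise nearly symmetric palpebral fissure
    if params.caruncle_radius > 0:
        car_cx = x_med + (1.0 if x_med > x_lat else -1.0) * params.caruncle_radius * 0.5
        caruncle = (xs - car_cx) ** 2 + (ys - y_med) ** 2 <= params.caruncle_radius**2
        layer[caruncle] = params.caruncle_intensity
    layer[fissure] = params.sclera_intensity
    pupil = fissure & ((xs - px) ** 2 + (ys - py) ** 2 <= params.pupil_radius**2)
    layer[pupil] = params.iris_intensity
    if params.epicanthus:
        fold_r = params.epicanthus_depth * params.canthal_width
        fold = fissure & ((xs - x_med) ** 2 + (ys - y_med) ** 2 <= fold_r**2)
        layer[fold] = params.skin_intensity
    layer[lid_line] = params.lid_intensity

    margin = 3.0
    bx = x_img_left - margin
    by = min(y_lat, y_med) - params.fissure_height / 2.0 - margin
    bw = (x_img_right - x_img_left) + 2 * margin
    bh = params.fissure_height + abs(y_lat - y_med) + 2 * margin
    box: Box = (bx, by, bw, bh)
    kp = OcularKeyPoints(
        lateral_canthus=(x_lat, y_lat), pupil_center=(px, py), medial_canthus=(x_med, y_med), eye=eye
    )
    return layer, kp, box


def render_image(
    params: SyntheticSubjectParams,
    severity: PlantedSeverity,
    rng: np.random.Generator,
    image_id: str = "synthetic",
) -> Tuple[AnnotatedImage, Dict[Laterality, Tuple[str, float, int]]]:
    """Render a full two-eye photograph.

    Returns the annotated image plus, per eye, the planted
    ``(movement, ratio, score)`` truth triple.
    """
    h, w = params.image_size
    canvas = np.full((h, w), params.skin_intensity)
    roles = movement_roles(severity.gaze)
    eyes: Dict[Laterality, EyeAnnotation] = {}
    truth: Dict[Laterality, Tuple[str, float, int]] = {}
    for eye in ("right", "left"):  # deterministic draw order
        movement = roles[eye]
        ratio = severity.resolve_ratio(movement, rng)
        layer, kp, box = render_eye(params, ratio, eye, severity.gaze, rng)
        mask = ~np.isnan(layer)
        canvas[mask] = layer[mask]
        eyes[eye] = EyeAnnotation(box=box, keypoints=kp)
        truth[eye] = (movement, ratio, score_from_ratio(ratio, movement))
    factor = 1.0 + rng.uniform(-params.brightness_jitter, params.brightness_jitter)
    canvas = canvas * factor + rng.normal(0.0, params.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)
    ann = AnnotatedImage(
        image_id=image_id, image=canvas, gaze=severity.gaze, eyes=eyes, provenance="synthetic"
    )
    ann.validate()
    return ann, truth


def _sample_params(base: SyntheticSubjectParams, rng: np.random.Generator) -> SyntheticSubjectParams:
    """Per-subject geometric variation around the base parameters."""
    return replace(
        base,
        canthal_width=float(base.canthal_width + rng.uniform(-6.0, 6.0)),
        fissure_height=float(base.fissure_height + rng.uniform(-3.0, 3.0)),
        interocular=float(base.interocular + rng.uniform(-8.0, 8.0)),
        canthal_tilt=float(base.canthal_tilt + rng.uniform(-1.5, 1.5)),
        pupil_radius=float(base.pupil_radius + rng.uniform(-1.0, 1.0)),
    )


def generate_annotated_images(
    n: int,
    seed: int,
    gaze: Literal["left", "right", "both"] = "both",
    scores: str = "uniform",
    base_params: Optional[SyntheticSubjectParams] = None,
) -> Tuple[List[AnnotatedImage], pd.DataFrame]:
    """Generate ``n`` annotated photographs in memory plus a truth table.

    ``scores`` is ``"uniform"`` (each movement's score drawn uniformly
    from 1..4) or ``"fixed:a,b"`` (fixed abduction score a, adduction
    score b).  The truth table has one row per (image, eye) with the
    planted movement, ratio and score.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_params or SyntheticSubjectParams()
    rng = np.random.default_rng(seed)
    fixed: Optional[Tuple[int, int]] = None
    if scores.startswith("fixed:"):
        a, b = (int(s) for s in scores.split(":", 1)[1].split(","))
        fixed = (a, b)
    elif scores != "uniform":
        raise ValueError(f"unknown score distribution {scores!r}")
    images: List[AnnotatedImage] = []
    rows = []
    for i in range(n):
        g: Laterality = gaze if gaze in ("left", "right") else ("left" if rng.integers(2) else "right")
        abd, add = fixed if fixed else (int(rng.integers(1, 5)), int(rng.integers(1, 5)))
        params = _sample_params(base, rng)
        image_id = f"img_{i:04d}_gaze{'L' if g == 'left' else 'R'}"
        ann, truth = render_image(
            params, PlantedSeverity(gaze=g, abduction_score=abd, adduction_score=add), rng, image_id
        )
        images.append(ann)
        for eye, (movement, ratio, score) in sorted(truth.items()):
            rows.append(
                {
                    "image_id": image_id,
                    "gaze": g,
                    "eye": eye,
                    "movement": movement,
                    "ratio": ratio,
                    "score": score,
                }
            )
    return images, pd.DataFrame(rows)


def generate_dataset(
    n: int,
    seed: int,
    out_dir: Path,
    gaze: Literal["left", "right", "both"] = "both",
    scores: str = "uniform",
    base_params: Optional[SyntheticSubjectParams] = None,
) -> pd.DataFrame:
    """Write a synthetic dataset (PNG + Labelme JSON + truth.csv) to disk.

    Regeneration with the same seed is byte-identical.  Returns the
    truth table (also written as ``truth.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, truth = generate_annotated_images(n, seed, gaze=gaze, scores=scores, base_params=base_params)
    for ann in images:
        save_image(ann.image, out_dir / f"{ann.image_id}.png")
        write_labelme(ann, out_dir / f"{ann.image_id}.json", image_path=f"{ann.image_id}.png")
    write_csv(truth, out_dir / "truth.csv")
    return truth
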