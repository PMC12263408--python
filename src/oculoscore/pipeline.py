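"""End-to-end scoring pipeline and score-table construction.

``run_pipeline`` walks a directory of lateral-gaze photographs, detects
both eyes and their keypoints, scores each eye's movement from the
canthal ratio, and writes one CSV row per (image, eye).  An undetected
eye yields a row with ``status=unscorable`` and the run continues.
``score_annotations`` is the manual-scoring path: it applies the same
geometry to human-annotated keypoints, so the two tables feed directly
into the agreement statistics.

Optional overlays reproduce the clinical readout: the detected eye box,
the three keypoints (medial canthus red, pupil center green, lateral
canthus blue) and the quartile region lines 1-4 between the canthi.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .detector.model import EyeDetector
from .detector.predict import EyeDetection, predict
from .io import AnnotatedImage, gaze_from_filename, load_image, write_csv
from .scoring import (
    Laterality,
    MovementScore,
    OcularKeyPoints,
    movement_roles,
    score_movement,
)

SCORE_COLUMNS = ["image_id", "gaze", "eye", "movement", "ratio", "score", "source", "status"]


def _score_rows(
    image_id: str,
    gaze: Laterality,
    keypoints: Dict[Laterality, Optional[OcularKeyPoints]],
    source: str,
) -> List[dict]:
    roles = movement_roles(gaze)
    rows = []
    for eye in ("right", "left"):
        kp = keypoints.get(eye)
        row = {
            "image_id": image_id,
            "gaze": gaze,
            "eye": eye,
            "movement": roles[eye],
            "source": source,
        }
        if kp is None:
            row.update(ratio=np.nan, score=pd.NA, status="unscorable")
        else:
            ms: MovementScore = score_movement(kp, roles[eye])
            row.update(ratio=ms.ratio, score=ms.score, status="ok")
        rows.append(row)
    return rows


def score_annotations(annotations: Iterable[AnnotatedImage], source: str = "manual") -> pd.DataFrame:
    """Score each annotated image from its ground-truth/manual keypoints."""
    rows: List[dict] = []
    for ann in annotations:
        if ann.gaze is None:
            warnings.warn(f"{ann.image_id}: no gaze direction; skipped", stacklevel=2)
            continue
        kps = {lat: eye.keypoints for lat, eye in ann.eyes.items()}
        rows.extend(_score_rows(ann.image_id, ann.gaze, kps, source))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def detections_to_keypoints(
    detections: Sequence[EyeDetection],
) -> Dict[Laterality, Optional[OcularKeyPoints]]:
    out: Dict[Laterality, Optional[OcularKeyPoints]] = {"left": None, "right": None}
    for det in detections:
        out[det.laterality] = det.keypoints
    return out


def quartile_lines(kp: OcularKeyPoints, movement: str) -> List[float]:
    """x-positions of the three quartile lines between the canthi,
    measured from the movement's target canthus."""
    x_lat, x_med = kp.lateral_canthus[0], kp.medial_canthus[0]
    x_target, x_other = (x_lat, x_med) if movement == "abduction" else (x_med, x_lat)
    return [x_target + f * (x_other - x_target) for f in (0.25, 0.5, 0.75)]


def render_overlay(
    image: np.ndarray, detections: Sequence[EyeDetection], gaze: Laterality
) -> Image.Image:
    """Draw boxes, keypoints and quartile region lines on a photograph."""
    im = Image.fromarray(np.clip(image, 0, 255).astype(np.uint8), mode="L").convert("RGB")
    draw = ImageDraw.Draw(im)
    roles = movement_roles(gaze)
    for det in detections:
        x, y, w, h = det.box
        draw.rectangle([x, y, x + w, y + h], outline=(0, 0, 255))
        for qx in quartile_lines(det.keypoints, roles[det.laterality]):
            draw.line([(qx, y), (qx, y + h)], fill=(255, 255, 0))
        for name, color in (
            ("medial_canthus", (255, 0, 0)),
            ("pupil_center", (0, 255, 0)),
            ("lateral_canthus", (0, 0, 255)),
        ):
            px, py = getattr(det.keypoints, name)
            draw.ellipse([px - 2, py - 2, px + 2, py + 2], fill=color)
    return im


def run_pipeline(
    images_dir: Path,
    model: EyeDetector,
    out_dir: Path,
    gaze_csv: Optional[Path] = None,
    overlays: bool = False,
) -> pd.DataFrame:
    """Detect, score and tabulate every photograph in a directory.

    Gaze direction comes from a ``_gazeL``/``_gazeR`` filename suffix
    or from a sidecar CSV with columns ``image_id, gaze``.  Writes
    ``scores.csv`` (and ``overlays/`` when requested) under ``out_dir``
    and returns the score table.
    """
    images_dir, out_dir = Path(images_dir), Path(out_dir)
    gaze_map: Dict[str, str] = {}
    if gaze_csv is not None:
        df = pd.read_csv(gaze_csv)
        gaze_map = dict(zip(df["image_id"].astype(str), df["gaze"].astype(str)))
    paths = sorted(p for p in images_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not paths:
        raise FileNotFoundError(f"no images found under {images_dir}")
    rows: List[dict] = []
    overlay_dir = out_dir / "overlays"
    for path in paths:
        image_id = path.stem
        gaze = gaze_map.get(image_id) or gaze_from_filename(path.name)
        if gaze is None:
            warnings.warn(f"{image_id}: unknown gaze direction; skipped", stacklevel=2)
            continue
        image = load_image(path)
        detections = predict(model, image)
        rows.extend(_score_rows(image_id, gaze, detections_to_keypoints(detections), "automatic"))
        if overlays:
            overlay_dir.mkdir(parents=True, exist_ok=True)
            render_overlay(image, detections, gaze).save(overlay_dir / f"{image_id}.png")
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(table, out_dir / "scores.csv")
    return table
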