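"""Readers/writers for annotated ocular photographs and score tables.

Annotations travel as Labelme-style JSON: one rectangle shape per eye
(label ``left_eye`` / ``right_eye``) and three point shapes per eye
(labels ``{left,right}_{lateral_canthus,pupil_center,medial_canthus}``).
Laterality prefixes refer to the patient's anatomy, not the image side.
Gaze direction is carried in the JSON ``flags`` (``gaze_left`` /
``gaze_right``) and, by convention, in a ``_gazeL`` / ``_gazeR``
filename suffix.

All file writes are atomic (temp file + rename), and JSON writing uses
sorted keys and a fixed float representation so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image

from .scoring import Laterality, OcularKeyPoints

KEYPOINT_LABELS = ("lateral_canthus", "pupil_center", "medial_canthus")

#: Box as (x, y, w, h) in pixels, origin top-left.
Box = Tuple[float, float, float, float]


@dataclass(frozen=True)
class EyeAnnotation:
    """Ground-truth (or predicted) box and landmarks of one eye."""

    box: Box
    keypoints: OcularKeyPoints


@dataclass
class AnnotatedImage:
    """One photograph with per-eye boxes/keypoints and gaze metadata."""

    image_id: str
    image: Optional[np.ndarray]  # (H, W) grayscale
    gaze: Optional[Laterality]
    eyes: Dict[Laterality, EyeAnnotation] = field(default_factory=dict)
    provenance: str = "manual"  # manual | synthetic | predicted

    @property
    def shape(self) -> Tuple[int, int]:
        if self.image is None:
            raise ValueError(f"{self.image_id}: no pixel data loaded")
        return self.image.shape[:2]

    def validate(self) -> None:
        if len(self.eyes) > 2:
            raise ValueError(f"{self.image_id}: more than two eyes annotated")
        if self.image is not None:
            h, w = self.shape
            for lat, eye in self.eyes.items():
                if eye.keypoints.eye != lat:
                    raise ValueError(f"{self.image_id}: laterality mismatch for {lat} eye")
                for name in KEYPOINT_LABELS:
                    x, y = getattr(eye.keypoints, name)
                    if not (0 <= x < w and 0 <= y < h):
                        raise ValueError(
                            f"{self.image_id}: {lat} {name} ({x:.1f}, {y:.1f}) outside image {w}x{h}"
                        )


def _atomic_write(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_image(image: np.ndarray, path: Path) -> None:
    """Write a grayscale image as PNG atomically."""
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    import io as _io

    buf = _io.BytesIO()
    Image.fromarray(arr, mode="L").save(buf, format="PNG")
    _atomic_write(Path(path), buf.getvalue())


def load_image(path: Path) -> np.ndarray:
    """Load an image as float grayscale (H, W) in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)


def gaze_from_filename(name: str) -> Optional[Laterality]:
    stem = Path(name).stem
    if stem.endswith("_gazeL"):
        return "left"
    if stem.endswith("_gazeR"):
        return "right"
    return None


def write_labelme(ann: AnnotatedImage, path: Path, image_path: Optional[str] = None) -> None:
    """Write an annotation as Labelme-style JSON (stable key order)."""
    if ann.image is None:
        raise ValueError(f"{ann.image_id}: image dimensions required to write annotation")
    h, w = ann.shape
    shapes = []
    for lat in sorted(ann.eyes):
        eye = ann.eyes[lat]
        x, y, bw, bh = eye.box
        shapes.append(
            {
                "label": f"{lat}_eye",
                "points": [[x, y], [x + bw, y + bh]],
                "shape_type": "rectangle",
                "group_id": None,
                "flags": {},
            }
        )
        for kp_name in KEYPOINT_LABELS:
            px, py = getattr(eye.keypoints, kp_name)
            shapes.append(
                {
                    "label": f"{lat}_{kp_name}",
                    "points": [[px, py]],
                    "shape_type": "point",
                    "group_id": None,
                    "flags": {},
                }
            )
    doc = {
        "version": "5.0.0",
        "flags": {"gaze_left": ann.gaze == "left", "gaze_right": ann.gaze == "right"},
        "shapes": shapes,
        "imagePath": image_path or f"{ann.image_id}.png",
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
        "provenance": ann.provenance,
    }
    data = json.dumps(doc, indent=2, sort_keys=True).encode()
    _atomic_write(Path(path), data)


def read_labelme(path: Path, load_pixels: bool = True) -> AnnotatedImage:
    """Parse a Labelme-style JSON annotation (optionally loading pixels).

    Unknown shape labels are skipped with a warning; a rectangle without
    its three keypoints (or vice versa) raises a validation error naming
    the eye and the missing label.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed annotation JSON: {exc}") from exc
    boxes: Dict[str, Box] = {}
    points: Dict[str, Tuple[float, float]] = {}
    for shape in doc.get("shapes", []):
        label = shape.get("label", "")
        stype = shape.get("shape_type")
        try:
            if stype == "rectangle" and label.endswith("_eye"):
                lat = label[: -len("_eye")]
                if lat not in ("left", "right"):
                    raise KeyError(label)
                (x0, y0), (x1, y1) = shape["points"]
                x, y = min(x0, x1), min(y0, y1)
                boxes[lat] = (x, y, abs(x1 - x0), abs(y1 - y0))
            elif stype == "point":
                lat, _, kp_name = label.partition("_")
                if lat not in ("left", "right") or kp_name not in KEYPOINT_LABELS:
                    raise KeyError(label)
                (px, py) = shape["points"][0]
                points[label] = (px, py)
            else:
                raise KeyError(label)
        except KeyError:
            warnings.warn(f"{path}: skipping unknown shape {label!r} ({stype})", stacklevel=2)
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed shape {label!r}: {exc}") from exc
    eyes: Dict[Laterality, EyeAnnotation] = {}
    for lat, box in sorted(boxes.items()):
        coords = {}
        for kp_name in KEYPOINT_LABELS:
            full = f"{lat}_{kp_name}"
            if full not in points:
                raise ValueError(f"{path}: {lat} eye is missing keypoint {kp_name!r}")
            coords[kp_name] = points[full]
        eyes[lat] = EyeAnnotation(box=box, keypoints=OcularKeyPoints(eye=lat, **coords))
    for label in points:
        lat = label.partition("_")[0]
        if lat not in boxes:
            raise ValueError(f"{path}: keypoint {label!r} has no {lat}_eye rectangle")
    flags = doc.get("flags", {})
    gaze: Optional[Laterality] = None
    if flags.get("gaze_left"):
        gaze = "left"
    elif flags.get("gaze_right"):
        gaze = "right"
    image = None
    if load_pixels:
        img_path = path.parent / doc.get("imagePath", "")
        if img_path.is_file():
            image = load_image(img_path)
    ann = AnnotatedImage(
        image_id=path.stem,
        image=image,
        gaze=gaze or gaze_from_filename(doc.get("imagePath", path.stem)),
        eyes=eyes,
        provenance=doc.get("provenance", "manual"),
    )
    if image is not None:
        ann.validate()
    return ann


def write_csv(df, path: Path) -> None:
    """Write a DataFrame as UTF-8 comma-separated CSV atomically."""
    data = df.to_csv(index=False).encode("utf-8")
    _atomic_write(Path(path), data)
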