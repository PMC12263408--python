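"""Canthal-ratio scoring of horizontal ocular movement disorders.

A lateral-gaze photograph is scored per eye from three landmarks: the
lateral canthus, the pupil center, and the medial canthus.  The movement
under test (abduction for the eye turning away from the nose, adduction
for the fellow eye) determines a *target* canthus — lateral for
abduction, medial for adduction.  The canthal ratio is the horizontal
distance from the pupil center to that target canthus, normalized by the
horizontal canthal width, and the integer severity score 1-4 is the
quartile bucket containing the ratio:

    score 1:        ratio <= 1/4      (excursion near-complete)
    score 2:  1/4 < ratio <= 1/2
    score 3:  1/2 < ratio <= 3/4
    score 4:        ratio >  3/4      (little or no excursion)

Only x-coordinates enter the ratio; vertical canthal disparity is
deliberately ignored.  Coordinates are 0-based pixels, origin top-left,
x increasing rightward.  Lateralities are anatomical (the patient's own
left/right); in an un-mirrored frontal photograph the patient's right
eye is therefore the leftmost in the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

Laterality = Literal["left", "right"]
Movement = Literal["abduction", "adduction"]

#: Upper edges of the score buckets (quartiles of canthal width).
SCORE_BREAKS: Tuple[float, float, float] = (0.25, 0.5, 0.75)

LATERALITIES: Tuple[Laterality, ...] = ("left", "right")
MOVEMENTS: Tuple[Movement, ...] = ("abduction", "adduction")


class DegenerateGeometryError(ValueError):
    """Raised when the canthal landmarks have zero horizontal width."""


@dataclass(frozen=True)
class OcularKeyPoints:
    """The three scoring landmarks of one eye, in pixel coordinates.

    Ordering is fixed system-wide as (lateral canthus, pupil center,
    medial canthus).
    """

    lateral_canthus: Tuple[float, float]
    pupil_center: Tuple[float, float]
    medial_canthus: Tuple[float, float]
    eye: Laterality

    def __post_init__(self) -> None:
        if self.eye not in LATERALITIES:
            raise ValueError(f"laterality must be 'left' or 'right', got {self.eye!r}")
        for name in ("lateral_canthus", "pupil_center", "medial_canthus"):
            x, y = getattr(self, name)
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"{name} has non-finite coordinates ({x}, {y})")
            # negative (out-of-frame) coordinates are representable so that
            # geometric transforms can produce candidates for the rotation
            # retry rule; annotations are bounds-checked at validation time

    def as_tuple(self) -> Tuple[float, float, float, float, float, float]:
        """(lx1, ly1, lx2, ly2, lx3, ly3) in the fixed landmark order."""
        return (*self.lateral_canthus, *self.pupil_center, *self.medial_canthus)


@dataclass(frozen=True)
class GazeDirection:
    """Direction of maximal horizontal gaze, in the patient's own frame."""

    direction: Laterality

    def __post_init__(self) -> None:
        if self.direction not in LATERALITIES:
            raise ValueError(f"gaze direction must be 'left' or 'right', got {self.direction!r}")


@dataclass(frozen=True)
class MovementScore:
    """Scored movement of one eye on one lateral-gaze photograph."""

    eye: Laterality
    movement: Movement
    ratio: float
    score: int

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")
        if self.score not in (1, 2, 3, 4):
            raise ValueError("score must be in 1..4")


def movement_roles(gaze: GazeDirection | str) -> dict:
    """Map each eye to the movement scored on this gaze photograph.

    The eye on the gazed-toward side abducts (moves temporally, toward
    its lateral canthus); the fellow eye adducts (moves nasally).
    """
    direction = gaze.direction if isinstance(gaze, GazeDirection) else gaze
    if direction not in LATERALITIES:
        raise ValueError(f"invalid gaze direction {direction!r}")
    other = "left" if direction == "right" else "right"
    return {direction: "abduction", other: "adduction"}


def canthal_ratio(kp: OcularKeyPoints, movement: Movement) -> float:
    """Normalized horizontal pupil-to-target-canthus distance.

    The target canthus is the one the pupil travels toward: lateral for
    abduction, medial for adduction.  The signed excursion shortfall is
    measured from the target toward the opposite canthus and clamped at
    zero, so a pupil that overshoots past the target still scores as a
    complete excursion (ratio 0), while a pupil that never leaves the
    opposite corner gives a ratio near (or beyond) 1.
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"movement must be 'abduction' or 'adduction', got {movement!r}")
    x_lat = kp.lateral_canthus[0]
    x_med = kp.medial_canthus[0]
    x_pup = kp.pupil_center[0]
    width = abs(x_lat - x_med)
    if width == 0:
        raise DegenerateGeometryError(
            f"zero horizontal canthal width for {kp.eye} eye (both canthi at x={x_lat})"
        )
    x_target, x_other = (x_lat, x_med) if movement == "abduction" else (x_med, x_lat)
    toward_other = 1.0 if x_other > x_target else -1.0
    signed = (x_pup - x_target) * toward_other / width
    return max(signed, 0.0)


def score_from_ratio(ratio: float, movement: Movement) -> int:
    """Bucket a canthal ratio into the 1-4 severity score.

    The buckets are identical for abduction (R1) and adduction (R2);
    each boundary belongs to the lower score (``<=`` on the upper edge).
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"movement must be 'abduction' or 'adduction', got {movement!r}")
    if not math.isfinite(ratio) or ratio < 0:
        raise ValueError(f"ratio must be finite and >= 0, got {ratio}")
    for score, upper in enumerate(SCORE_BREAKS, start=1):
        if ratio <= upper:
            return score
    return 4


def score_movement(kp: OcularKeyPoints, movement: Movement) -> MovementScore:
    """Score one eye's movement from its keypoints."""
    ratio = canthal_ratio(kp, movement)
    return MovementScore(eye=kp.eye, movement=movement, ratio=ratio, score=score_from_ratio(ratio, movement))


def score_gaze_image(
    kp_left: Optional[OcularKeyPoints],
    kp_right: Optional[OcularKeyPoints],
    gaze: GazeDirection | str,
) -> Tuple[Optional[MovementScore], Optional[MovementScore]]:
    """Score both eyes of one lateral-gaze photograph.

    Returns ``(left_eye_score, right_eye_score)``; a missing eye yields
    ``None`` in its slot (unscorable) while the other eye is still
    scored.  One of the two scores is an abduction score and the other
    an adduction score, per :func:`movement_roles`.
    """
    roles = movement_roles(gaze)
    out = {}
    for kp in (kp_left, kp_right):
        if kp is None:
            continue
        out[kp.eye] = score_movement(kp, roles[kp.eye])
    if kp_left is not None and kp_right is not None and kp_left.eye == kp_right.eye:
        raise ValueError("kp_left and kp_right carry the same laterality")
    return out.get("left"), out.get("right")
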