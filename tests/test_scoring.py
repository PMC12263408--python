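"""Canthal-ratio scoring: movement roles, ratio geometry, score buckets."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculoscore.scoring import (
    DegenerateGeometryError,
    GazeDirection,
    OcularKeyPoints,
    canthal_ratio,
    movement_roles,
    score_from_ratio,
    score_gaze_image,
)


def kp(x_lat, x_pup, x_med, eye="right", y=(50.0, 50.0, 50.0)):
    return OcularKeyPoints(
        lateral_canthus=(x_lat, y[0]), pupil_center=(x_pup, y[1]), medial_canthus=(x_med, y[2]), eye=eye
    )


def score_oracle(ratio):
    """Brute-force quartile bucket lookup."""
    if ratio <= 0.25:
        return 1
    if ratio <= 0.5:
        return 2
    if ratio <= 0.75:
        return 3
    return 4


class TestMovementRoles:
    def test_right_gaze_scores_right_abduction_left_adduction(self):
        assert movement_roles(GazeDirection("right")) == {"right": "abduction", "left": "adduction"}

    def test_left_gaze_scores_left_abduction_right_adduction(self):
        assert movement_roles("left") == {"left": "abduction", "right": "adduction"}

    def test_roles_are_laterality_mirrors(self):
        r, l = movement_roles("right"), movement_roles("left")
        assert r == {("left" if k == "right" else "right"): v for k, v in l.items()}

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            movement_roles("up")


class TestCanthalRatio:
    @pytest.mark.parametrize(
        "x_lat,x_pup,x_med,movement,expected",
        [
            (200, 175, 100, "abduction", 0.25),
            (200, 200, 100, "abduction", 0.0),  # pupil at target canthus
            (200, 130, 100, "adduction", 0.30),
            (100, 130, 200, "abduction", 0.30),  # mirrored eye
        ],
    )
    def test_normalized_horizontal_distance(self, x_lat, x_pup, x_med, movement, expected):
        assert canthal_ratio(kp(x_lat, x_pup, x_med), movement) == pytest.approx(expected)

    def test_overshoot_past_target_clamps_to_zero(self):
        assert canthal_ratio(kp(200, 210, 100), "abduction") == 0.0

    def test_pupil_beyond_opposite_canthus_exceeds_one(self):
        assert canthal_ratio(kp(200, 90, 100), "abduction") > 1.0

    def test_zero_canthal_width_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            canthal_ratio(kp(150, 150, 150), "abduction")

    def test_unknown_movement_rejected(self):
        with pytest.raises(ValueError):
            canthal_ratio(kp(200, 150, 100), "elevation")

    def test_vertical_disparity_is_ignored(self):
        flat = canthal_ratio(kp(200, 150, 100), "abduction")
        tilted = canthal_ratio(kp(200, 150, 100, y=(40.0, 55.0, 62.0)), "abduction")
        assert flat == tilted


class TestScoreFromRatio:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.0, 1), (0.20, 1), (0.25, 1), (0.26, 2), (0.5, 2), (0.51, 3), (0.60, 3), (0.75, 3), (0.80, 4), (1.2, 4)],
    )
    def test_quartile_buckets_with_inclusive_upper_edges(self, ratio, expected):
        assert score_from_ratio(ratio, "abduction") == expected
        assert score_from_ratio(ratio, "adduction") == expected  # identical buckets

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            score_from_ratio(-0.1, "abduction")

    def test_sweep_matches_bucket_oracle(self):
        for i in range(0, 121):
            r = i / 100.0
            for movement in ("abduction", "adduction"):
                assert score_from_ratio(r, movement) == score_oracle(r)

    @given(st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_exactly_one_score_and_monotone(self, ratio):
        s = score_from_ratio(ratio, "abduction")
        assert s in (1, 2, 3, 4)
        assert score_from_ratio(ratio + 0.01, "abduction") >= s


class TestScoreGazeImage:
    def test_full_excursions_score_one_each(self):
        # gaze right: right pupil at its lateral canthus, left pupil at its medial canthus
        right = kp(100, 100, 170, eye="right")
        left = kp(250, 180, 180, eye="left")
        ls, rs = score_gaze_image(left, right, "right")
        assert (rs.movement, rs.score) == ("abduction", 1)
        assert (ls.movement, ls.score) == ("adduction", 1)

    def test_partial_abduction_bucket(self):
        right = kp(100, 142, 170, eye="right")  # ratio 0.6
        left = kp(250, 180, 180, eye="left")
        _, rs = score_gaze_image(left, right, "right")
        assert rs.ratio == pytest.approx(0.6)
        assert rs.score == 3

    def test_missing_eye_is_unscorable_other_still_scored(self):
        right = kp(100, 120, 170, eye="right")
        ls, rs = score_gaze_image(None, right, "right")
        assert ls is None and rs is not None

    def test_duplicate_laterality_rejected(self):
        a, b = kp(100, 120, 170, eye="right"), kp(100, 120, 170, eye="right")
        with pytest.raises(ValueError):
            score_gaze_image(a, b, "right")


coords = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)


@given(x_lat=coords, x_med=coords, t=st.floats(0, 1), shift=st.floats(0, 100), scale=st.floats(0.1, 10))
@settings(max_examples=200, derandomize=True)
def test_ratio_invariant_under_translation_and_scale(x_lat, x_med, t, shift, scale):
    if abs(x_lat - x_med) < 1e-6:
        return
    x_pup = x_med + t * (x_lat - x_med)
    base = canthal_ratio(kp(x_lat, x_pup, x_med), "abduction")
    shifted = canthal_ratio(kp(x_lat + shift, x_pup + shift, x_med + shift), "abduction")
    scaled = canthal_ratio(kp(x_lat * scale, x_pup * scale, x_med * scale), "abduction")
    assert math.isclose(base, shifted, abs_tol=1e-6)
    assert math.isclose(base, scaled, abs_tol=1e-6)


@given(x_lat=coords, x_med=coords, t=st.floats(0, 1))
@settings(max_examples=200, derandomize=True)
def test_mirror_symmetry_of_image_scores(x_lat, x_med, t):
    """Reflecting all x about a vertical axis and swapping gaze + lateralities
    leaves both movement scores unchanged."""
    if abs(x_lat - x_med) < 1e-6:
        return
    x_pup = x_med + t * (x_lat - x_med)
    width = 600.0
    right = kp(x_lat, x_pup, x_med, eye="right")
    left = kp(width - x_lat, width - x_pup, width - x_med, eye="left")
    # mirrored image: lateralities swap, gaze flips
    ls1, rs1 = score_gaze_image(left, right, "right")
    ls2, rs2 = score_gaze_image(
        kp(x_lat, x_pup, x_med, eye="left"),
        kp(width - x_lat, width - x_pup, width - x_med, eye="right"),
        "left",
    )
    assert (rs1.score, ls1.score) == (ls2.score, rs2.score)
    assert rs1.ratio == pytest.approx(ls2.ratio, abs=1e-9)
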