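"""Agreement statistics vs independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from oculoscore.stats import (
    PairingError,
    agreement_report,
    interpret_kappa,
    mean_euclidean_distance,
    spearman,
    weighted_kappa,
)


def kappa_oracle(a, b, weights="linear"):
    """Explicit 4x4 contingency-table computation, written independently."""
    table = [[0.0] * 4 for _ in range(4)]
    for x, y in zip(a, b):
        table[x - 1][y - 1] += 1
    n = len(a)
    row = [sum(table[i]) for i in range(4)]
    col = [sum(table[i][j] for i in range(4)) for j in range(4)]
    num = den = 0.0
    for i in range(4):
        for j in range(4):
            w = abs(i - j) if weights == "linear" else (i - j) ** 2
            num += w * table[i][j]
            den += w * row[i] * col[j] / n
    return 1.0 - num / den


def spearman_oracle(a, b):
    """Average ranks, then a hand-written Pearson correlation."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    ra, rb = ranks(list(a)), ranks(list(b))
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    cov = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    va = sum((x - ma) ** 2 for x in ra)
    vb = sum((y - mb) ** 2 for y in rb)
    return cov / (va**0.5 * vb**0.5)


def points_frame(pts):
    return pd.DataFrame(
        [
            {"image_id": f"im{i}", "eye": "left", "keypoint": "pupil_center", "x": x, "y": y}
            for i, (x, y) in enumerate(pts)
        ]
    )


class TestMeanEuclideanDistance:
    def test_identical_points_give_zero(self):
        f = points_frame([(1.0, 2.0), (3.0, 4.0)])
        (s,) = mean_euclidean_distance(f, f.copy())
        assert s.mean_distance == 0.0 and s.n == 2

    def test_three_four_five_triangle(self):
        (s,) = mean_euclidean_distance(points_frame([(0.0, 0.0)]), points_frame([(3.0, 4.0)]))
        assert s.mean_distance == 5.0

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            p = rng.uniform(0, 100, size=(n, 2))
            q = rng.uniform(0, 100, size=(n, 2))
            (s,) = mean_euclidean_distance(points_frame(p), points_frame(q))
            expected = sum(((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) ** 0.5 for a, b in zip(p, q)) / n
            assert s.mean_distance == pytest.approx(expected, abs=1e-9)

    def test_translation_invariance_and_linear_scaling(self, rng):
        p = rng.uniform(0, 50, size=(6, 2))
        q = rng.uniform(0, 50, size=(6, 2))
        (base,) = mean_euclidean_distance(points_frame(p), points_frame(q))
        (moved,) = mean_euclidean_distance(points_frame(p + 13.5), points_frame(q + 13.5))
        (scaled,) = mean_euclidean_distance(points_frame(p * 3), points_frame(q * 3))
        assert moved.mean_distance == pytest.approx(base.mean_distance, abs=1e-9)
        assert scaled.mean_distance == pytest.approx(3 * base.mean_distance, abs=1e-9)

    def test_unpaired_records_are_reported(self):
        a = points_frame([(0.0, 0.0), (1.0, 1.0)])
        with pytest.raises(PairingError, match="unpaired"):
            mean_euclidean_distance(a, a.iloc[:1])


class TestWeightedKappa:
    def test_identical_vectors_give_exactly_one(self):
        v = [1, 2, 3, 4, 2, 3]
        assert weighted_kappa(v, v) == 1.0

    def test_marginal_product_table_gives_zero(self):
        # contingency table equal to its own marginal product: O == E
        a = [1, 1, 2, 2] * 4
        b = [1, 2] * 8
        assert weighted_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_matches_table_oracle(self):
        a = [1, 2, 3, 4, 2, 3, 1, 4]
        b = [1, 2, 3, 3, 2, 4, 2, 4]
        assert weighted_kappa(a, b, "linear") == pytest.approx(kappa_oracle(a, b, "linear"), abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_random_fixtures_match_oracle(self, weights, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            a = rng.integers(1, 5, size=n).tolist()
            b = rng.integers(1, 5, size=n).tolist()
            try:
                expected = kappa_oracle(a, b, weights)
            except ZeroDivisionError:
                continue
            assert weighted_kappa(a, b, weights) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for weights, sk in (("linear", "linear"), ("quadratic", "quadratic")):
            a = rng.integers(1, 5, size=60)
            b = rng.integers(1, 5, size=60)
            assert weighted_kappa(a, b, weights) == pytest.approx(
                cohen_kappa_score(a, b, weights=sk, labels=[1, 2, 3, 4]), abs=1e-12
            )

    def test_symmetry_in_raters(self, rng):
        a = rng.integers(1, 5, size=30)
        b = rng.integers(1, 5, size=30)
        assert weighted_kappa(a, b) == pytest.approx(weighted_kappa(b, a), abs=1e-12)

    def test_constant_identical_raters_define_kappa_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert weighted_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            weighted_kappa([1, 5], [1, 2])


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (1.0, "complete agreement"),
            (0.857, "high consistency"),
            (0.75, "high consistency"),
            (0.5, "moderate consistency"),
            (0.4, "moderate consistency"),
            (0.2, "low consistency"),
            (0.0, "complete disagreement"),
            (-0.3, "below chance"),
        ],
    )
    def test_bands(self, kappa, band):
        assert interpret_kappa(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestSpearman:
    def test_identical_distinct_vectors_give_one(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_rank_order_gives_minus_one(self):
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3]) == pytest.approx(-1.0)

    def test_tie_laden_vectors_match_rank_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            a = rng.integers(1, 5, size=n).tolist()
            b = rng.integers(1, 5, size=n).tolist()
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert spearman(a, b) == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman([2, 2, 2, 2], [1, 2, 3, 4])


def scores_frame(scores, movements, source):
    return pd.DataFrame(
        [
            {"image_id": f"im{i // 2}", "eye": "left" if i % 2 else "right", "movement": m, "score": s}
            for i, (s, m) in enumerate(zip(scores, movements))
        ]
    )


class TestAgreementReport:
    def test_copied_scores_give_complete_agreement_everywhere(self, rng):
        scores = rng.integers(1, 5, size=40).tolist()
        movements = (["abduction", "adduction"] * 20)[:40]
        m = scores_frame(scores, movements, "manual")
        a = scores_frame(scores, movements, "automatic")
        results = agreement_report(m, a)
        assert {r.stratum for r in results} == {"all", "abduction", "adduction"}
        for r in results:
            assert r.kappa == 1.0 and r.band == "complete agreement"
            assert r.rho == pytest.approx(1.0) or np.isnan(r.rho)

    def test_stratum_counts_match_row_filters(self, rng):
        scores = rng.integers(1, 5, size=60).tolist()
        movements = [("abduction" if rng.uniform() < 0.6 else "adduction") for _ in range(60)]
        m = scores_frame(scores, movements, "manual")
        a = scores_frame(rng.integers(1, 5, size=60).tolist(), movements, "automatic")
        results = {r.stratum: r for r in agreement_report(m, a)}
        assert results["all"].n == 60
        assert results["abduction"].n == sum(1 for x in movements if x == "abduction")
        assert results["adduction"].n == sum(1 for x in movements if x == "adduction")

    def test_empty_stratum_skipped_with_warning(self):
        scores = [1, 2, 3, 4]
        movements = ["abduction"] * 4
        m = scores_frame(scores, movements, "manual")
        a = scores_frame(scores, movements, "automatic")
        with pytest.warns(UserWarning, match="adduction"):
            results = agreement_report(m, a)
        assert {r.stratum for r in results} == {"all", "abduction"}
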