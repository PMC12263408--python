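"""Agreement and accuracy statistics for keypoint detection and scoring.

Three quantities summarize how well automatic scoring tracks manual
annotation:

* per-(eye, keypoint) mean Euclidean distance (MED) in pixels between
  predicted and annotated landmark coordinates — lower is more accurate;
* the weighted kappa coefficient between the two raters' ordinal 1-4
  scores, with the conventional interpretation bands (>= 0.75 high,
  0.4-0.75 moderate, < 0.4 low consistency);
* the Spearman rank correlation between the two score vectors.

Kappa is computed from the 4x4 contingency table with marginal-product
expected counts, ``kappa = 1 - sum(w*O) / sum(w*E)``, using linear
disagreement weights by default (quadratic available).  Spearman uses
tie-aware average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .scoring import Laterality

KEYPOINT_NAMES = ("lateral_canthus", "pupil_center", "medial_canthus")
WeightScheme = Literal["linear", "quadratic"]


class PairingError(ValueError):
    """Raised when predicted and annotated records cannot be paired 1:1."""


@dataclass(frozen=True)
class KeypointErrorSummary:
    """MED of one (eye, keypoint) group, with dispersion across images.

    ``sd`` is the standard deviation of the per-image distances and
    ``sem`` its standard error; both are reported because either may be
    meant by a "mean +/- dispersion" table.
    """

    eye: Laterality
    keypoint: str
    mean_distance: float
    sd: float
    sem: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement between two score vectors in a stratum."""

    stratum: str
    kappa: float
    rho: float
    n: int
    band: str


def mean_euclidean_distance(
    predicted: pd.DataFrame, annotated: pd.DataFrame
) -> List[KeypointErrorSummary]:
    """Per-(eye, keypoint) mean Euclidean pixel distance.

    Both frames need columns ``image_id, eye, keypoint, x, y``; rows are
    paired on ``(image_id, eye, keypoint)`` and every row must have
    exactly one partner.
    """
    key = ["image_id", "eye", "keypoint"]
    for name, df in (("predicted", predicted), ("annotated", annotated)):
        missing = set(key + ["x", "y"]) - set(df.columns)
        if missing:
            raise PairingError(f"{name} frame lacks columns {sorted(missing)}")
        if df.duplicated(key).any():
            dupes = df.loc[df.duplicated(key), key].to_records(index=False).tolist()
            raise PairingError(f"duplicate {name} records: {dupes}")
    merged = predicted.merge(annotated, on=key, how="outer", suffixes=("_p", "_a"), indicator=True)
    unpaired = merged[merged["_merge"] != "both"]
    if len(unpaired):
        offenders = unpaired[key + ["_merge"]].to_records(index=False).tolist()
        raise PairingError(f"unpaired records: {offenders}")
    d = np.hypot(merged["x_p"] - merged["x_a"], merged["y_p"] - merged["y_a"])
    merged = merged.assign(distance=d)
    out = []
    for (eye, kp), grp in merged.groupby(["eye", "keypoint"], sort=True):
        dist = grp["distance"].to_numpy()
        out.append(
            KeypointErrorSummary(
                eye=eye,
                keypoint=kp,
                mean_distance=float(dist.mean()),
                sd=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
                sem=float(dist.std(ddof=1) / np.sqrt(len(dist))) if len(dist) > 1 else 0.0,
                n=len(dist),
            )
        )
    return out


def _kappa_weights(scheme: WeightScheme, k: int) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == "linear":
        return np.abs(i - j).astype(float)
    if scheme == "quadratic":
        return ((i - j) ** 2).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    weights: WeightScheme = "linear",
    categories: Tuple[int, ...] = (1, 2, 3, 4),
) -> float:
    """Weighted kappa between two raters' ordinal scores.

    ``kappa = 1`` means complete agreement; ``0`` agreement no better
    than chance.  Larger score discrepancies are penalized more heavily
    (linearly or quadratically in the category distance).  If both
    raters are constant and identical the expected disagreement is zero;
    kappa is then defined as 1 (with a warning), since agreement is
    complete.
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired scores")
    cats = np.asarray(categories)
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        bad = sorted(set(np.concatenate([a, b]).tolist()) - set(cats.tolist()))
        raise ValueError(f"scores outside categories {tuple(cats)}: {bad}")
    k = len(cats)
    ia = np.searchsorted(cats, a)
    ib = np.searchsorted(cats, b)
    observed = np.zeros((k, k))
    np.add.at(observed, (ia, ib), 1.0)
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    w = _kappa_weights(weights, k)
    denom = float((w * expected).sum())
    if denom == 0.0:
        warnings.warn(
            "both raters constant and identical: expected disagreement is zero, kappa defined as 1",
            stacklevel=2,
        )
        return 1.0
    return float(1.0 - (w * observed).sum() / denom)


def interpret_kappa(kappa: float) -> str:
    """Conventional consistency band for a weighted kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa == 1.0:
        return "complete agreement"
    if kappa >= 0.75:
        return "high consistency"
    if kappa >= 0.4:
        return "moderate consistency"
    if kappa > 0.0:
        return "low consistency"
    if kappa == 0.0:
        return "complete disagreement"
    return "below chance"


def spearman(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Raises ``ValueError`` when either vector has zero rank variance
    (a constant vector has no defined rank correlation).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired scores")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("Spearman correlation undefined: a vector has zero rank variance")
    rho = _sps.spearmanr(a, b).statistic
    return float(rho)


def agreement_report(
    manual: pd.DataFrame,
    automatic: pd.DataFrame,
    strata: Iterable[str] = ("all", "abduction", "adduction"),
    weights: WeightScheme = "linear",
) -> List[AgreementResult]:
    """Kappa/Spearman agreement per movement stratum.

    Both frames need columns ``image_id, eye, movement, score``; rows
    are paired on ``(image_id, eye)``.  Strata are ``all`` plus the two
    movement types; an empty stratum is skipped with a warning, and a
    stratum where Spearman is undefined reports ``rho = nan``.
    """
    key = ["image_id", "eye"]
    for name, df in (("manual", manual), ("automatic", automatic)):
        missing = {"image_id", "eye", "movement", "score"} - set(df.columns)
        if missing:
            raise PairingError(f"{name} frame lacks columns {sorted(missing)}")
    merged = manual.merge(automatic, on=key, how="inner", suffixes=("_m", "_a"))
    if not len(merged):
        raise PairingError("manual and automatic frames share no (image_id, eye) pairs")
    results = []
    for stratum in strata:
        sub = merged if stratum == "all" else merged[merged["movement_m"] == stratum]
        if len(sub) < 2:
            warnings.warn(f"stratum {stratum!r} has fewer than 2 pairs; skipped", stacklevel=2)
            continue
        kap = weighted_kappa(sub["score_m"].to_numpy(), sub["score_a"].to_numpy(), weights=weights)
        try:
            rho = spearman(sub["score_m"].to_numpy(), sub["score_a"].to_numpy())
        except ValueError as exc:
            warnings.warn(f"stratum {stratum!r}: {exc}", stacklevel=2)
            rho = float("nan")
        results.append(
            AgreementResult(stratum=stratum, kappa=kap, rho=rho, n=len(sub), band=interpret_kappa(kap))
        )
    return results


def agreement_results_frame(results: List[AgreementResult]) -> pd.DataFrame:
    """Tabulate agreement results (one row per stratum)."""
    return pd.DataFrame(
        [{"stratum": r.stratum, "n": r.n, "kappa": r.kappa, "rho": r.rho, "band": r.band} for r in results]
    )


def keypoint_errors_frame(summaries: List[KeypointErrorSummary]) -> pd.DataFrame:
    """Tabulate MED summaries (one row per eye x keypoint)."""
    return pd.DataFrame(
        [
            {
                "eye": s.eye,
                "keypoint": s.keypoint,
                "mean_distance": s.mean_distance,
                "sd": s.sd,
                "sem": s.sem,
                "n": s.n,
            }
            for s in summaries
        ]
    )
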