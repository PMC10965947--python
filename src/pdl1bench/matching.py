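"""Distance-gated point matching (the "hit criterion") and confusion counts.

A prediction can hit a reference point only within a fixed radius (8 um by
default, the average nucleus diameter); among candidates the closest
prediction takes the hit. The default semantics are a symmetric, global
closest-first one-to-one matching: all reference-prediction pairs within the
radius are sorted by distance and accepted greedily whenever neither member
is already matched. A reference-sided variant (each reference takes its
closest prediction, predictions reusable) is available for sensitivity
analysis.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import (
    AnnotationSet,
    CellClass,
    ConfusionMatrix,
    MatchResult,
    MatchedPair,
)

__all__ = [
    "match_points",
    "confusion_from_match",
    "background_disagreement_fraction",
]


def _lex_ranks(coords: np.ndarray) -> np.ndarray:
    """Rank of each point under lexicographic (y, x) order."""
    order = np.lexsort((coords[:, 0], coords[:, 1]))  # primary y, secondary x
    ranks = np.empty(len(coords), dtype=np.int64)
    ranks[order] = np.arange(len(coords))
    return ranks


def match_points(
    reference: AnnotationSet,
    prediction: AnnotationSet,
    radius_um: float = 8.0,
    mode: str = "one-to-one",
) -> MatchResult:
    """Match predictions to references under the hit criterion.

    Parameters
    ----------
    reference, prediction
        Point sets on the same ROI (same micrometers frame; ``roi_id`` must
        agree).
    radius_um
        Hit radius; a pair at distance exactly equal to the radius counts as
        a hit.
    mode
        ``"one-to-one"`` (default): global closest-first greedy matching;
        each point participates in at most one pair, and the pair set is
        independent of which set is called the reference.
        ``"reference-sided"``: every reference takes its closest in-radius
        prediction; a prediction may serve several references.

    Distance ties are broken by (reference rank, prediction rank), ranks
    taken from sorting each point set lexicographically by (y, x).
    """
    if reference.roi_id != prediction.roi_id:
        raise ValueError(
            f"cannot match across ROIs: {reference.roi_id!r} vs {prediction.roi_id!r}"
        )
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if mode not in ("one-to-one", "reference-sided"):
        raise ValueError(f"unknown matching mode: {mode!r}")

    ref_xy = reference.coords()
    pred_xy = prediction.coords()
    n_ref, n_pred = len(ref_xy), len(pred_xy)
    if n_ref == 0 or n_pred == 0:
        return MatchResult(
            pairs=[],
            unmatched_refs=list(reference.points),
            unmatched_preds=list(prediction.points),
            radius_um=radius_um,
        )

    # Candidate pairs within the gate, via a KD-tree range query.
    tree = cKDTree(pred_xy)
    neighbors = tree.query_ball_point(ref_xy, r=radius_um)
    ref_ranks = _lex_ranks(ref_xy)
    pred_ranks = _lex_ranks(pred_xy)

    candidates: list[tuple[float, int, int, int, int]] = []
    for i, js in enumerate(neighbors):
        for j in js:
            d = math.dist(ref_xy[i], pred_xy[j])
            candidates.append((d, ref_ranks[i], pred_ranks[j], i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    pairs: list[MatchedPair] = []
    if mode == "one-to-one":
        ref_used = np.zeros(n_ref, dtype=bool)
        pred_used = np.zeros(n_pred, dtype=bool)
        for d, _, _, i, j in candidates:
            if not ref_used[i] and not pred_used[j]:
                ref_used[i] = pred_used[j] = True
                pairs.append(MatchedPair(reference.points[i], prediction.points[j], d))
    else:  # reference-sided: closest prediction per reference, reuse allowed
        ref_used = np.zeros(n_ref, dtype=bool)
        pred_used = np.zeros(n_pred, dtype=bool)
        best: dict[int, tuple[float, int, int]] = {}
        for d, rr, pr, i, j in candidates:
            key = (d, pr)
            if i not in best or key < best[i][:2]:
                best[i] = (d, pr, j)
        for i in sorted(best, key=lambda i: ref_ranks[i]):
            d, _, j = best[i]
            ref_used[i] = True
            pred_used[j] = True
            pairs.append(MatchedPair(reference.points[i], prediction.points[j], d))

    unmatched_refs = [p for p, used in zip(reference.points, ref_used) if not used]
    unmatched_preds = [p for p, used in zip(prediction.points, pred_used) if not used]
    return MatchResult(
        pairs=pairs,
        unmatched_refs=unmatched_refs,
        unmatched_preds=unmatched_preds,
        radius_um=radius_um,
    )


def confusion_from_match(match: MatchResult) -> ConfusionMatrix:
    """Tally a match result into a 4-class confusion matrix.

    Matched pairs count as (reference class, prediction class); unmatched
    references as (class, BACKGROUND); unmatched predictions as
    (BACKGROUND, class). Points must be labeled.
    """
    conf = ConfusionMatrix()
    for pair in match.pairs:
        if pair.reference.label is None or pair.prediction.label is None:
            raise ValueError("confusion requires labeled points")
        conf.increment(pair.reference.label, pair.prediction.label)
    for p in match.unmatched_refs:
        if p.label is None:
            raise ValueError("confusion requires labeled points")
        conf.increment(p.label, CellClass.BACKGROUND)
    for p in match.unmatched_preds:
        if p.label is None:
            raise ValueError("confusion requires labeled points")
        conf.increment(CellClass.BACKGROUND, p.label)
    return conf


def background_disagreement_fraction(conf: ConfusionMatrix) -> float:
    """Fraction of disagreements that are presence/absence disagreements.

    Disagreements are all off-diagonal counts (including the background row
    and column); the background share is the sum of the background row and
    column. Returns NaN when there are no disagreements at all (the fraction
    is undefined, never silently 0).
    """
    counts = conf.counts
    off_diag = counts.sum() - np.trace(counts)
    if off_diag == 0:
        return float("nan")
    bg = conf.index(CellClass.BACKGROUND)
    background = counts[bg, :].sum() + counts[:, bg].sum()
    return float(background / off_diag)
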