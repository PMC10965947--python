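"""Cell-level F1 metrics over hit-criterion confusion matrices.

Per-class F1 is 2*TP / (2*TP + FP + FN): for class c, TP is the (c, c)
confusion count, FP the rest of column c (the prediction said c while the
reference disagreed or saw background), FN the rest of row c. The macro
score averages the per-class F1 over the classes for which it is defined.

Pairwise matrices over a panel of sources (readers and a detector) support
two pooling granularities: summing TP/FP/FN over all shared ROIs before the
ratio ("pooled"), or pooling within each case and averaging case-level macro
F1 across cases ("per_case", the default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationSet, CellClass, ConfusionMatrix, POINT_CLASSES
from .matching import confusion_from_match, match_points

__all__ = [
    "ClassScore",
    "F1Report",
    "PairwiseMatrix",
    "GroupSummary",
    "f1_from_confusions",
    "pairwise_f1",
    "summarize_groups",
]


@dataclass(frozen=True)
class ClassScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")


@dataclass
class F1Report:
    """Per-class and macro F1 pooled over a collection of confusion matrices."""

    per_class: dict[CellClass, ClassScore]
    n_confusions: int

    @property
    def undefined_classes(self) -> list[CellClass]:
        """Classes absent from both sides everywhere (F1 undefined, excluded)."""
        return [c for c, s in self.per_class.items() if math.isnan(s.f1)]

    @property
    def macro_f1(self) -> float:
        defined = [s.f1 for s in self.per_class.values() if not math.isnan(s.f1)]
        return float(np.mean(defined)) if defined else float("nan")

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "undefined_classes": [c.value for c in self.undefined_classes],
            "per_class": {
                c.value: {
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "precision": s.precision,
                    "recall": s.recall,
                    "f1": s.f1,
                }
                for c, s in self.per_class.items()
            },
            "n_confusions": self.n_confusions,
        }


def f1_from_confusions(confusions: Sequence[ConfusionMatrix]) -> F1Report:
    """Pool confusion matrices by summation, then compute per-class F1.

    TP/FP/FN are summed across ROIs before any ratio is taken (micro pooling
    per class). A class with no events on either side anywhere has an
    undefined F1; it is excluded from the macro mean and flagged.
    """
    if not confusions:
        raise ValueError("need at least one confusion matrix")
    total = confusions[0]
    for c in confusions[1:]:
        total = total + c
    counts = total.counts
    per_class: dict[CellClass, ClassScore] = {}
    for cls in POINT_CLASSES:
        k = total.index(cls)
        tp = int(counts[k, k])
        fp = int(counts[:, k].sum() - counts[k, k])
        fn = int(counts[k, :].sum() - counts[k, k])
        per_class[cls] = ClassScore(tp=tp, fp=fp, fn=fn)
    return F1Report(per_class=per_class, n_confusions=len(confusions))


@dataclass
class PairwiseMatrix:
    """Symmetric macro-F1 matrix over a panel of sources (diagonal = 1)."""

    sources: list[str]
    values: pd.DataFrame
    mode: str
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = np.isfinite(v) & np.isfinite(v.T)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T], atol=1e-12):
            raise ValueError("pairwise matrix must be symmetric")

    def pair_values(
        self, group_a: Sequence[str], group_b: Optional[Sequence[str]] = None
    ) -> list[float]:
        """Off-diagonal entries between two source groups (or within one)."""
        out = []
        if group_b is None:
            pairs = combinations(group_a, 2)
        else:
            pairs = ((a, b) for a in group_a for b in group_b if a != b)
        for a, b in pairs:
            out.append(float(self.values.loc[a, b]))
        return out


def _macro_from_sets(
    sets_a: Mapping[str, AnnotationSet],
    sets_b: Mapping[str, AnnotationSet],
    shared: Sequence[str],
    radius_um: float,
    mode: str,
    case_of: Mapping[str, str],
) -> float:
    by_case: dict[str, list[ConfusionMatrix]] = {}
    for roi in shared:
        m = match_points(sets_a[roi], sets_b[roi], radius_um=radius_um)
        by_case.setdefault(case_of[roi], []).append(confusion_from_match(m))
    if mode == "pooled":
        all_confs = [c for confs in by_case.values() for c in confs]
        return f1_from_confusions(all_confs).macro_f1
    # per_case: pool within a case, average case-level macro F1 across cases
    case_scores = [
        f1_from_confusions(confs).macro_f1 for confs in by_case.values()
    ]
    defined = [s for s in case_scores if not math.isnan(s)]
    return float(np.mean(defined)) if defined else float("nan")


def pairwise_f1(
    sets: Mapping[str, Mapping[str, AnnotationSet]],
    radius_um: float = 8.0,
    mode: str = "per_case",
    case_of: Optional[Mapping[str, str]] = None,
) -> PairwiseMatrix:
    """Pairwise macro-F1 matrix over a panel of sources.

    Parameters
    ----------
    sets
        source id -> (ROI id -> AnnotationSet).
    radius_um
        Hit radius passed to :func:`match_points`.
    mode
        ``"per_case"`` (default): pool confusions within each case, average
        case-level macro F1 across cases. ``"pooled"``: sum TP/FP/FN over
        all shared ROIs before the ratio.
    case_of
        ROI id -> case id. When omitted, each ROI is its own case.

    Pairs of sources with no shared ROI get a NaN entry and are listed in
    ``missing_pairs`` (never reported as 0).
    """
    if mode not in ("per_case", "pooled"):
        raise ValueError(f"unknown mode: {mode!r}")
    sources = list(sets)
    values = pd.DataFrame(np.eye(len(sources)), index=sources, columns=sources, dtype=float)
    missing: list[tuple[str, str]] = []
    for a, b in combinations(sources, 2):
        shared = sorted(set(sets[a]) & set(sets[b]))
        if not shared:
            values.loc[a, b] = values.loc[b, a] = float("nan")
            missing.append((a, b))
            continue
        cmap = {r: (case_of[r] if case_of is not None else r) for r in shared}
        f1 = _macro_from_sets(sets[a], sets[b], shared, radius_um, mode, cmap)
        values.loc[a, b] = values.loc[b, a] = f1
    return PairwiseMatrix(sources=sources, values=values, mode=mode, missing_pairs=missing)


@dataclass
class GroupSummary:
    """Mean with a 1.96*SD interval, gated by a Shapiro-Wilk normality test.

    The interval mean +/- 1.96*SD is reported when the group passes
    Shapiro-Wilk at the 0.05 level (groups too small to test are treated as
    normal); otherwise the group is flagged non-normal and summarized by
    median and range.
    """

    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    normal: bool
    shapiro_p: Optional[float]
    median: float
    range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "normal": self.normal,
            "shapiro_p": self.shapiro_p,
            "median": self.median,
            "range": list(self.range),
        }


def summarize_groups(values: Sequence[float], alpha: float = 0.05) -> GroupSummary:
    """Summarize a group of scores as mean +/- 1.96*SD (normality-gated)."""
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if len(vals) == 0:
        raise ValueError("empty group")
    if len(vals) < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    shapiro_p: Optional[float] = None
    normal = True
    if len(vals) >= 3 and sd > 0:
        shapiro_p = float(stats.shapiro(vals).pvalue)
        normal = shapiro_p >= alpha
    return GroupSummary(
        n=len(vals),
        mean=mean,
        sd=sd,
        ci_low=mean - 1.96 * sd,
        ci_high=mean + 1.96 * sd,
        normal=normal,
        shapiro_p=shapiro_p,
        median=float(np.median(vals)),
        range=(float(vals.min()), float(vals.max())),
    )
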