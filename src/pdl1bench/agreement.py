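"""Slide-level TPS quantification and interobserver agreement statistics.

The tumor proportion score (TPS) is the percentage of PD-L1 positive tumor
cells among all tumor cells; 'other' cells never enter the ratio. Clinical
reporting discretizes TPS at <1%, 1-49% and >=50%.

Agreement battery:

* linear weighted Cohen's kappa over the three clinical categories
  (weights ``w_ij = 1 - |i - j| / (k - 1)``, chance agreement from marginal
  products);
* unweighted Cohen's kappa after binarizing at a single cutoff;
* ICC(2,1): single-rater intraclass correlation from a two-way random
  effects ANOVA with absolute agreement, with the exact F-based confidence
  interval;
* Bland-Altman mean difference and 1.96*SD limits of agreement;
* per-reader agreement with the majority vote of the other readers
  (a reader's own rating never enters their reference majority).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationSet, CellClass, TPSRecord

__all__ = [
    "TPS_CATEGORIES",
    "TPSUndefinedError",
    "compute_tps",
    "discretize_tps",
    "linear_kappa",
    "kappa_at_cutoff",
    "ICCResult",
    "icc_2_1",
    "BlandAltmanResult",
    "bland_altman",
    "MajorityVoteResult",
    "majority_vote_agreement",
]

#: Ordered clinical TPS categories with integer codes 0, 1, 2.
TPS_CATEGORIES: tuple[str, ...] = ("<1%", "1-49%", ">=50%")


class TPSUndefinedError(ValueError):
    """Raised when TPS is requested for a sample without tumor cells."""


def compute_tps(
    detections: Union[AnnotationSet, Sequence[AnnotationSet]],
    case_id: Optional[str] = None,
    source_id: Optional[str] = None,
) -> TPSRecord:
    """Compute the tumor proportion score from labeled detections.

    Accepts one annotation set or several (e.g. all ROIs of a case); counts
    are pooled. OTHER cells are ignored by construction. Zero tumor cells
    raise :class:`TPSUndefinedError` — a slide-level QC concern that must
    never silently read as TPS 0.
    """
    sets = [detections] if isinstance(detections, AnnotationSet) else list(detections)
    if not sets:
        raise ValueError("need at least one annotation set")
    n_pos = n_neg = 0
    for s in sets:
        s.require_labeled()
        for p in s.points:
            if p.label is CellClass.POS_TUMOR:
                n_pos += 1
            elif p.label is CellClass.NEG_TUMOR:
                n_neg += 1
    if n_pos + n_neg == 0:
        raise TPSUndefinedError(
            "TPS undefined: no tumor cells detected (QC concern, not a 0% score)"
        )
    return TPSRecord(
        case_id=case_id if case_id is not None else sets[0].roi_id,
        source_id=source_id if source_id is not None else sets[0].source_id,
        tps_pct=100.0 * n_pos / (n_pos + n_neg),
        n_pos_tumor=n_pos,
        n_neg_tumor=n_neg,
    )


def discretize_tps(tps_pct: float) -> int:
    """Map a TPS percentage to its clinical category code.

    tps < 1 -> 0 ("<1%"); 1 <= tps < 50 -> 1 ("1-49%"); tps >= 50 -> 2
    (">=50%"). Both middle-band boundaries include their lower bound.
    """
    if not (0.0 <= tps_pct <= 100.0):
        raise ValueError(f"TPS must lie in [0, 100], got {tps_pct}")
    if tps_pct < 1.0:
        return 0
    if tps_pct < 50.0:
        return 1
    return 2


def _kappa_from_codes(a: np.ndarray, b: np.ndarray, n_categories: int, linear: bool) -> float:
    """Cohen's kappa from paired category codes.

    Degenerate marginals follow the convention: a rater with zero marginal
    variance and perfect agreement gives kappa 1; zero variance with
    imperfect agreement is undefined (NaN).
    """
    n = len(a)
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        return 1.0 if np.array_equal(a, b) else float("nan")
    k = n_categories
    table = np.zeros((k, k), dtype=float)
    for i, j in zip(a, b):
        table[i, j] += 1
    p = table / n
    if linear and k > 2:
        idx = np.arange(k)
        w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    else:
        w = np.eye(k)
    po = float((w * p).sum())
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    pe = float((w * np.outer(pa, pb)).sum())
    if 1.0 - pe < 1e-15:
        return 1.0 if po >= 1.0 - 1e-15 else float("nan")
    return (po - pe) / (1.0 - pe)


def linear_kappa(
    ratings_a: Sequence[int], ratings_b: Sequence[int], n_categories: int = 3
) -> float:
    """Linear weighted Cohen's kappa over ordinal category codes.

    Weights are ``w_ij = 1 - |i - j| / (k - 1)``; chance agreement comes
    from the product of the two raters' marginals. With ``k = 2`` the
    weights collapse to 0/1 and the statistic equals unweighted kappa.
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 rated cases")
    if a.min() < 0 or b.min() < 0 or a.max() >= n_categories or b.max() >= n_categories:
        raise ValueError(f"category codes must lie in [0, {n_categories - 1}]")
    return _kappa_from_codes(a, b, n_categories, linear=True)


def kappa_at_cutoff(
    tps_a: Sequence[float], tps_b: Sequence[float], cutoff: float
) -> float:
    """Unweighted Cohen's kappa after binarizing TPS at a cutoff (>= positive).

    When every case falls on the same side of the cutoff for both raters
    the statistic carries no information about the cutoff and is reported
    as undefined (NaN), even though the raters nominally agree.
    """
    a = (np.asarray(tps_a, dtype=float) >= cutoff).astype(int)
    b = (np.asarray(tps_b, dtype=float) >= cutoff).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length series of at least 2 cases")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return float("nan")
    return _kappa_from_codes(a, b, 2, linear=False)


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n_cases: int
    n_raters: int
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_raters": self.n_raters,
            "n_dropped": self.n_dropped,
        }


def icc_2_1(matrix: Union[np.ndarray, pd.DataFrame], alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the two-way ANOVA decomposition with rows = cases and columns =
    raters (mean squares MSR for rows, MSC for columns, MSE residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval is the exact F-based interval for this
    estimator (two-way random, absolute agreement, single rater) using a
    Satterthwaite-approximated denominator degrees of freedom. Rows with
    any missing value are dropped (counted in ``n_dropped``).

    Zero between-case variance makes the coefficient undefined; the result
    carries NaN.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (cases x raters)")
    keep = ~np.isnan(x).any(axis=1)
    n_dropped = int((~keep).sum())
    x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 cases and 2 raters with complete data")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    # Exact inter-rater agreement leaves only floating-point cancellation
    # noise in the residual and rater sums of squares; snap to ICC = 1.
    if ss_total > 0 and ss_err <= 1e-10 * ss_total and ss_cols <= 1e-10 * ss_total:
        return ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, k, n_dropped)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_rows <= 1e-12 * max(ss_total, 1e-300) or abs(denom) < 1e-300:
        return ICCResult(float("nan"), float("nan"), float("nan"), msr, msc, mse, n, k, n_dropped)
    icc = (msr - mse) / denom

    # Exact F-based interval (two-way random, absolute agreement, single rater).
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    if math.isinf(a) or mse == 0.0:
        return ICCResult(float(icc), float(icc), float(icc), msr, msc, mse, n, k, n_dropped)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return ICCResult(float(icc), float(lower), float(upper), msr, msc, mse, n, k, n_dropped)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def bland_altman(series_a: Sequence[float], series_b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement: mean of a-b and 1.96*SD limits of agreement."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length series of at least 2 values")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=len(d),
    )


@dataclass
class MajorityVoteResult:
    source: str
    cutoff: float
    kappa: float
    n_cases_used: int
    n_ties: int

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "cutoff": self.cutoff,
            "kappa": self.kappa,
            "n_cases_used": self.n_cases_used,
            "n_ties": self.n_ties,
        }


def majority_vote_agreement(
    tps_table: pd.DataFrame,
    target: str,
    cutoff: float,
    readers: Optional[Sequence[str]] = None,
    tie_rule: str = "drop",
) -> MajorityVoteResult:
    """Kappa of one source against the majority vote of the human readers.

    ``tps_table`` is cases x sources of TPS percentages. ``readers`` names
    the human reader columns forming the majority (default: every column
    except the target); the target is always excluded from its own majority
    reference, so a reader is never compared against a vote containing their
    own rating. Ratings are binarized at ``cutoff`` before voting.

    Ties (possible with an even voter count) are dropped from the comparison
    by default and counted; ``tie_rule="higher"`` breaks them toward the
    positive category instead.
    """
    if tie_rule not in ("drop", "higher"):
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    if target not in tps_table.columns:
        raise ValueError(f"target {target!r} not in table")
    voters = [c for c in (readers if readers is not None else tps_table.columns) if c != target]
    if len(voters) < 2:
        raise ValueError("need at least 2 voting readers besides the target")

    votes = (tps_table[voters].to_numpy(dtype=float) >= cutoff).astype(int)
    target_bin = (tps_table[target].to_numpy(dtype=float) >= cutoff).astype(int)
    pos = votes.sum(axis=1)
    neg = votes.shape[1] - pos
    tie = pos == neg
    majority = (pos > neg).astype(int)
    if tie_rule == "higher":
        majority[tie] = 1
        keep = np.ones(len(majority), dtype=bool)
    else:
        keep = ~tie
    n_ties = int(tie.sum())
    if keep.sum() < 2:
        raise ValueError("fewer than 2 untied cases; majority-vote kappa undefined")
    kappa = _kappa_from_codes(target_bin[keep], majority[keep], 2, linear=False)
    return MajorityVoteResult(
        source=target,
        cutoff=cutoff,
        kappa=kappa,
        n_cases_used=int(keep.sum()),
        n_ties=n_ties,
    )
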