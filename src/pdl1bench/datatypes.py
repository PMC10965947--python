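"""Core value types shared across the benchmarking pipeline.

Coordinate convention (project-wide): continuous micrometer coordinates with
the origin at the ROI top-left corner, x increasing rightward and y downward.
Pixel ``(i, j)`` of a raster with spacing ``s`` um/px has its center at
``((j + 0.5) * s, (i + 0.5) * s)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class CellClass(str, enum.Enum):
    """Cell classes of the three-class PD-L1 annotation scheme.

    ``BACKGROUND`` is a bookkeeping sentinel used only in confusion matrices
    to record presence/absence disagreements; it never appears on a point.
    """

    NEG_TUMOR = "neg_tumor"
    POS_TUMOR = "pos_tumor"
    OTHER = "other"
    BACKGROUND = "background"

    def __str__(self) -> str:  # CSV/JSON friendliness
        return self.value


#: The three labels a point may carry, in canonical order.
POINT_CLASSES: tuple[CellClass, ...] = (
    CellClass.NEG_TUMOR,
    CellClass.POS_TUMOR,
    CellClass.OTHER,
)

#: Confusion-matrix axis order (point classes plus the background sentinel).
CONFUSION_CLASSES: tuple[CellClass, ...] = POINT_CLASSES + (CellClass.BACKGROUND,)


def parse_cell_class(label: str) -> CellClass:
    """Parse a class label string, rejecting unknown labels."""
    try:
        cls = CellClass(str(label).strip().lower())
    except ValueError:
        raise ValueError(f"unknown cell class label: {label!r}") from None
    if cls is CellClass.BACKGROUND:
        raise ValueError("'background' is a confusion-matrix sentinel, not a point label")
    return cls


@dataclass(frozen=True)
class CellPoint:
    """One point annotation or detection in micrometer coordinates.

    ``label`` may be ``None`` only for class-agnostic nuclei detections that
    have not yet been assigned a class; every labeled context (annotation
    sets entering matching or serialization) requires one of the three
    non-sentinel classes.
    """

    x_um: float
    y_um: float
    label: Optional[CellClass] = None
    confidence: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label is CellClass.BACKGROUND:
            raise ValueError("a CellPoint cannot carry the BACKGROUND sentinel")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    def moved(self, x_um: float, y_um: float) -> "CellPoint":
        return replace(self, x_um=x_um, y_um=y_um)


@dataclass
class AnnotationSet:
    """All points of one source (a reader or a detector) on one ROI."""

    roi_id: str
    source_id: str
    points: list[CellPoint]
    width_um: Optional[float] = None
    height_um: Optional[float] = None
    spacing_um_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width_um is not None and self.width_um <= 0:
            raise ValueError("width_um must be positive")
        if self.height_um is not None and self.height_um <= 0:
            raise ValueError("height_um must be positive")
        if self.spacing_um_per_px is not None and self.spacing_um_per_px <= 0:
            raise ValueError("spacing_um_per_px must be positive")

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        """Point coordinates as an (n, 2) float array of (x_um, y_um)."""
        if not self.points:
            return np.empty((0, 2), dtype=float)
        return np.array([(p.x_um, p.y_um) for p in self.points], dtype=float)

    def labels(self) -> list[Optional[CellClass]]:
        return [p.label for p in self.points]

    def require_labeled(self) -> None:
        n_missing = sum(1 for p in self.points if p.label is None)
        if n_missing:
            raise ValueError(
                f"annotation set {self.source_id!r} on ROI {self.roi_id!r} has "
                f"{n_missing} unlabeled point(s)"
            )


@dataclass
class GroundTruthROI:
    """A simulated ROI: geometry, ground-truth cells, optional rendering."""

    width_um: float
    height_um: float
    spacing_um_per_px: float
    cells: list[CellPoint]
    seed: int
    image: Optional[np.ndarray] = None  # (H, W, 3) uint8 when rendered
    roi_id: str = "roi"

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1.0e6

    def as_annotation_set(self, source_id: str = "truth") -> AnnotationSet:
        return AnnotationSet(
            roi_id=self.roi_id,
            source_id=source_id,
            points=[replace(p, source=source_id) for p in self.cells],
            width_um=self.width_um,
            height_um=self.height_um,
            spacing_um_per_px=self.spacing_um_per_px,
        )


def _as_class_map(value, name: str) -> dict[CellClass, float]:
    if isinstance(value, dict):
        out = {CellClass(k) if not isinstance(k, CellClass) else k: float(v) for k, v in value.items()}
    else:
        out = {c: float(value) for c in POINT_CLASSES}
    missing = [c for c in POINT_CLASSES if c not in out]
    if missing:
        raise ValueError(f"{name} missing entries for {missing}")
    return out


@dataclass
class ReaderModel:
    """Statistical model of one annotator's errors on a point pattern.

    Parameters
    ----------
    miss_rate
        Per-class probability of not annotating a true cell at all; a scalar
        applies to every class.
    confusion
        3x3 row-stochastic matrix over (NEG_TUMOR, POS_TUMOR, OTHER): row =
        true class, column = reported class.
    jitter_sigma_um
        Isotropic Gaussian localization noise, in micrometers.
    extra_rate_per_mm2
        Intensity of spurious (hallucinated) points, as a homogeneous Poisson
        process over the ROI area.
    extra_class_probs
        Class distribution of spurious points (length 3, sums to 1).
    """

    miss_rate: dict[CellClass, float] | float = 0.0
    confusion: np.ndarray | Sequence[Sequence[float]] = None  # type: ignore[assignment]
    jitter_sigma_um: float = 0.0
    extra_rate_per_mm2: float = 0.0
    extra_class_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        self.miss_rate = _as_class_map(self.miss_rate, "miss_rate")
        for c, r in self.miss_rate.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"miss_rate[{c}] = {r} outside [0, 1]")
        if self.confusion is None:
            self.confusion = np.eye(3)
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (3, 3):
            raise ValueError("confusion must be 3x3")
        if np.any(self.confusion < -1e-12):
            raise ValueError("confusion entries must be non-negative")
        rowsums = self.confusion.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(f"confusion rows must sum to 1, got {rowsums}")
        if self.jitter_sigma_um < 0:
            raise ValueError("jitter_sigma_um must be >= 0")
        if self.extra_rate_per_mm2 < 0:
            raise ValueError("extra_rate_per_mm2 must be >= 0")
        self.extra_class_probs = np.asarray(self.extra_class_probs, dtype=float)
        if self.extra_class_probs.shape != (3,) or abs(self.extra_class_probs.sum() - 1.0) > 1e-9:
            raise ValueError("extra_class_probs must be length 3 and sum to 1")

    @classmethod
    def noiseless(cls) -> "ReaderModel":
        return cls(miss_rate=0.0, confusion=np.eye(3), jitter_sigma_um=0.0, extra_rate_per_mm2=0.0)


@dataclass
class TPSPanel:
    """Slide-level visual TPS estimates of a reader panel.

    ``estimates`` is a cases x readers DataFrame of TPS percentages, each a
    multiple of ``increment_pct``.
    """

    cases: list[str]
    true_tps: np.ndarray
    estimates: pd.DataFrame
    increment_pct: float = 5.0

    def __post_init__(self) -> None:
        self.true_tps = np.asarray(self.true_tps, dtype=float)
        vals = self.estimates.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError("TPS estimates must lie in [0, 100]")
        mult = vals / self.increment_pct
        if not np.allclose(mult, np.round(mult), atol=1e-9):
            raise ValueError(f"estimates must be multiples of {self.increment_pct}%")


@dataclass(frozen=True)
class MatchedPair:
    reference: CellPoint
    prediction: CellPoint
    distance_um: float


@dataclass
class MatchResult:
    """Outcome of hit-criterion matching between two point sets."""

    pairs: list[MatchedPair]
    unmatched_refs: list[CellPoint]
    unmatched_preds: list[CellPoint]
    radius_um: float

    @property
    def n_refs(self) -> int:
        return len(self.pairs) + len(self.unmatched_refs)

    @property
    def n_preds(self) -> int:
        return len(self.pairs) + len(self.unmatched_preds)


class ConfusionMatrix:
    """4x4 integer counts over (NEG_TUMOR, POS_TUMOR, OTHER, BACKGROUND).

    Rows index the reference source, columns the prediction source. The
    (BACKGROUND, BACKGROUND) cell is structurally zero: a point absent from
    both sources is not an event.
    """

    classes = CONFUSION_CLASSES

    def __init__(self, counts: Optional[np.ndarray] = None) -> None:
        if counts is None:
            counts = np.zeros((4, 4), dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (4, 4):
            raise ValueError("confusion matrix must be 4x4")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        bg = self.classes.index(CellClass.BACKGROUND)
        if counts[bg, bg] != 0:
            raise ValueError("(BACKGROUND, BACKGROUND) must be structurally zero")
        self.counts = counts

    def index(self, cls: CellClass) -> int:
        return self.classes.index(cls)

    def increment(self, ref: CellClass, pred: CellClass) -> None:
        if ref is CellClass.BACKGROUND and pred is CellClass.BACKGROUND:
            raise ValueError("cannot count a (BACKGROUND, BACKGROUND) event")
        self.counts[self.index(ref), self.index(pred)] += 1

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConfusionMatrix) and np.array_equal(self.counts, other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts.T.copy())

    def to_dataframe(self) -> pd.DataFrame:
        names = [c.value for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        names = [c.value for c in cls.classes]
        return cls(df.loc[names, names].to_numpy())

    def __repr__(self) -> str:
        return f"ConfusionMatrix(total={self.total})\n{self.to_dataframe()}"


@dataclass(frozen=True)
class LabeledPolygon:
    """A free-hand region of homogeneous cell type, as a closed simple ring."""

    vertices: tuple[tuple[float, float], ...]
    label: CellClass
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        if self.label not in POINT_CLASSES:
            raise ValueError("polygon label must be one of the three point classes")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len({v for v in verts}) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", verts)


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned square detection box centered on a point annotation."""

    x_um: float
    y_um: float
    side_um: float = 20.0
    label: Optional[CellClass] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise ValueError("side_um must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in micrometers."""
        h = self.side_um / 2.0
        return (self.x_um - h, self.x_um + h, self.y_um - h, self.y_um + h)


@dataclass
class TPSRecord:
    """One slide-level tumor proportion score of one source on one case."""

    case_id: str
    source_id: str
    tps_pct: float
    n_pos_tumor: Optional[int] = None
    n_neg_tumor: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tps_pct <= 100.0):
            raise ValueError("tps_pct must lie in [0, 100]")
        if self.n_pos_tumor is not None and self.n_neg_tumor is not None:
            n_pos, n_neg = self.n_pos_tumor, self.n_neg_tumor
            if n_pos < 0 or n_neg < 0 or n_pos + n_neg == 0:
                raise ValueError("tumor counts must be non-negative with a positive sum")
            expected = 100.0 * n_pos / (n_pos + n_neg)
            if abs(expected - self.tps_pct) > 1e-9:
                raise ValueError(
                    f"tps_pct {self.tps_pct} inconsistent with counts {n_pos}/{n_neg}"
                )
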