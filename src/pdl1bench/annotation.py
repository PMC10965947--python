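"""Two-step semi-automatic annotation: detect nucleus centers, transfer labels.

Step 1 finds class-agnostic nucleus centers on an IHC image; step 2
intersects the detected points with free-hand labeled polygons and assigns
each point the class of its containing region. Around the detector, point
annotations convert to 20x20 um bounding boxes and back (box centers are
the detection locations).

The nucleus detector here is a classical stand-in — color deconvolution of
the hematoxylin channel followed by multi-scale Laplacian-of-Gaussian blob
detection — standing in for a learned detector, which is out of scope. Its
failure modes differ from a CNN's (e.g. each lobe of a multinucleated cell
is detected separately; that behavior is accepted, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.feature import peak_local_max

from .datatypes import (
    AnnotationSet,
    CellClass,
    CellPoint,
    DetectionBox,
    LabeledPolygon,
)
from .synthetic import DAB_OD, HEMATOXYLIN_OD

__all__ = [
    "StainMatrixError",
    "PolygonOverlapError",
    "DetectorParams",
    "separate_stains",
    "detect_nuclei",
    "label_points_by_polygons",
    "points_to_boxes",
    "boxes_to_points",
]


class StainMatrixError(ValueError):
    """Stain matrix is singular or too ill-conditioned to unmix."""


class PolygonOverlapError(ValueError):
    """Strict mode: points fall inside overlapping polygons of different classes."""

    def __init__(self, offending: list[CellPoint]):
        self.offending = offending
        super().__init__(
            f"{len(offending)} point(s) inside overlapping polygons with "
            f"conflicting classes (strict mode)"
        )


def _default_stain_matrix() -> np.ndarray:
    return np.vstack([HEMATOXYLIN_OD, DAB_OD])


def separate_stains(
    image: np.ndarray,
    stain_matrix: Optional[np.ndarray] = None,
    max_condition: float = 1e6,
) -> dict[str, np.ndarray]:
    """Unmix an RGB IHC image into per-stain density maps.

    The image is converted to optical density (``OD = -log10(I / I0)`` per
    channel, white = zero absorbance) and decomposed by least squares onto
    the stain vectors. The default matrix holds the Ruifrok-Johnston
    hematoxylin and DAB vectors; a third residual vector orthogonal to both
    is appended automatically when only two rows are given.

    Returns a dict with keys ``"hematoxylin"``, ``"dab"`` (and
    ``"residual"``), each a non-negative float map with the raster
    dimensions of the input.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    m = _default_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] not in (2, 3):
        raise StainMatrixError("stain matrix must be 2x3 or 3x3")
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms < 1e-12):
        raise StainMatrixError("stain matrix has a zero row")
    m = m / norms[:, None]
    names = ["hematoxylin", "dab", "residual"][: m.shape[0]]
    if m.shape[0] == 2:
        resid = np.cross(m[0], m[1])
        if np.linalg.norm(resid) < 1e-8:
            raise StainMatrixError("stain vectors are parallel")
        m = np.vstack([m, resid / np.linalg.norm(resid)])
        names = ["hematoxylin", "dab", "residual"]
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > max_condition:
        raise StainMatrixError(f"stain matrix condition number {cond:.3g} too high")

    scale = 255.0 if img.dtype == np.uint8 else 1.0
    intensity = np.clip(img.astype(float) / scale, 1e-6, 1.0)
    od = -np.log10(intensity)
    # OD = C @ M  =>  C = OD @ pinv(M)
    conc = od.reshape(-1, 3) @ np.linalg.pinv(m)
    conc = np.clip(conc, 0.0, None).reshape(img.shape[0], img.shape[1], m.shape[0])
    return {name: conc[..., i] for i, name in enumerate(names)}


@dataclass(frozen=True)
class DetectorParams:
    """Stand-in nucleus detector parameters.

    Scale range spans nucleus diameters of roughly 3-10 um: a LoG filter of
    scale sigma responds maximally to a blob of radius ``sigma * sqrt(2)``,
    so sigmas of 1.0-3.6 um cover that diameter range.
    """

    min_sigma_um: float = 1.0
    max_sigma_um: float = 3.6
    n_scales: int = 5
    min_prominence: float = 0.05
    min_sep_um: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.min_sigma_um <= self.max_sigma_um):
            raise ValueError("need 0 < min_sigma_um <= max_sigma_um")
        if self.n_scales < 1 or self.min_prominence <= 0 or self.min_sep_um <= 0:
            raise ValueError("detector parameters must be positive")


def detect_nuclei(
    image: np.ndarray,
    spacing_um_per_px: float,
    params: DetectorParams = DetectorParams(),
    stain_matrix: Optional[np.ndarray] = None,
) -> list[CellPoint]:
    """Detect nucleus centers on an IHC image (class-agnostic).

    Runs scale-normalized Laplacian-of-Gaussian filtering on the unmixed
    hematoxylin density map over the configured scale range, takes the
    maximum response over scales, and keeps local maxima above
    ``min_prominence`` with non-maximum suppression at ``min_sep_um``.
    Centers are returned in micrometers (pixel (i, j) center =
    ((j+0.5) s, (i+0.5) s)).
    """
    if spacing_um_per_px <= 0:
        raise ValueError("spacing must be positive")
    hem = separate_stains(image, stain_matrix=stain_matrix)["hematoxylin"]
    sigmas_um = np.linspace(params.min_sigma_um, params.max_sigma_um, params.n_scales)
    response = np.full(hem.shape, -np.inf)
    for sigma_um in sigmas_um:
        sigma_px = sigma_um / spacing_um_per_px
        # Scale-normalized negative LoG: positive at blob centers.
        r = -(sigma_px**2) * ndimage.gaussian_laplace(hem, sigma=sigma_px)
        response = np.maximum(response, r)

    min_dist_px = max(1, int(round(params.min_sep_um / spacing_um_per_px)))
    peaks = peak_local_max(
        response,
        min_distance=min_dist_px,
        threshold_abs=params.min_prominence,
        exclude_border=False,
    )
    s = spacing_um_per_px
    points = [
        CellPoint(float((j + 0.5) * s), float((i + 0.5) * s), label=None, source="detector")
        for i, j in peaks
    ]
    points.sort(key=lambda p: (p.y_um, p.x_um))
    return points


def label_points_by_polygons(
    points: Sequence[CellPoint],
    polygons: Sequence[LabeledPolygon],
    tie_rule: str = "smallest_area",
    outside: str = "discard",
    roi_id: Optional[str] = None,
    source_id: str = "semiauto",
    width_um: Optional[float] = None,
    height_um: Optional[float] = None,
    spacing_um_per_px: Optional[float] = None,
) -> AnnotationSet:
    """Assign each detected point the class of its containing polygon.

    Boundary points count as inside. A point inside several polygons takes
    the class of the smallest-area one under the default tie rule (free-hand
    annotators refine inside larger regions); ``tie_rule="strict"`` raises
    :class:`PolygonOverlapError` instead when the containing classes
    conflict. Points inside no polygon are discarded by default
    (``outside="other"`` keeps them as OTHER instead). Output points are
    sorted by (y, x); the operation never invents points.
    """
    if tie_rule not in ("smallest_area", "strict"):
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    if outside not in ("discard", "other"):
        raise ValueError(f"unknown outside rule: {outside!r}")

    shapes: list[tuple[ShapelyPolygon, LabeledPolygon]] = []
    for poly in polygons:
        sp = ShapelyPolygon(poly.vertices)
        if not sp.is_valid or sp.area <= 0:
            raise ValueError(f"invalid polygon (self-intersecting or degenerate): {poly}")
        shapes.append((sp, poly))

    labeled: list[CellPoint] = []
    offending: list[CellPoint] = []
    for pt in points:
        sp_pt = ShapelyPoint(pt.x_um, pt.y_um)
        hits = [(sp.area, lp) for sp, lp in shapes if sp.covers(sp_pt)]
        if not hits:
            if outside == "other":
                labeled.append(replace(pt, label=CellClass.OTHER, source=source_id))
            continue
        classes = {lp.label for _, lp in hits}
        if len(classes) > 1 and tie_rule == "strict":
            offending.append(pt)
            continue
        _, winner = min(hits, key=lambda h: h[0])
        labeled.append(replace(pt, label=winner.label, source=source_id))
    if offending:
        raise PolygonOverlapError(offending)

    labeled.sort(key=lambda p: (p.y_um, p.x_um))
    rid = roi_id if roi_id is not None else (polygons[0].roi_id if polygons else "roi")
    return AnnotationSet(
        roi_id=rid,
        source_id=source_id,
        points=labeled,
        width_um=width_um,
        height_um=height_um,
        spacing_um_per_px=spacing_um_per_px,
    )


def points_to_boxes(points: Sequence[CellPoint], side_um: float = 20.0) -> list[DetectionBox]:
    """Extend point annotations to square bounding boxes centered on them."""
    if side_um <= 0:
        raise ValueError("side_um must be positive")
    return [
        DetectionBox(p.x_um, p.y_um, side_um=side_um, label=p.label, confidence=p.confidence)
        for p in points
    ]


def boxes_to_points(boxes: Sequence[DetectionBox]) -> list[CellPoint]:
    """Collapse detection boxes back to their center points."""
    return [
        CellPoint(b.x_um, b.y_um, label=b.label, confidence=b.confidence) for b in boxes
    ]
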