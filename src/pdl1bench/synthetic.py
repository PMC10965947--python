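"""Synthetic multi-reader study generator.

Emulates the raw material of a PD-L1 cell-level reader study: hard-core
point patterns of tumor and non-tumor cells on small ROIs, optional
IHC-like renderings (hematoxylin-toned nuclei, DAB-toned membrane rings on
PD-L1 positive tumor cells), per-reader annotation noise, and panels of
visual slide-level TPS estimates rounded to clinical increments.

All operations are deterministic for a fixed (parameters, seed) pair: the
per-cell random draws happen in a documented fixed order so outputs are
stable across platforms.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationSet,
    CellClass,
    CellPoint,
    GroundTruthROI,
    POINT_CLASSES,
    ReaderModel,
    TPSPanel,
)

__all__ = [
    "PackingError",
    "generate_tissue_roi",
    "render_ihc_image",
    "simulate_reader",
    "expected_recall_under_jitter",
    "simulate_tps_panel",
    "round_to_increment",
    "HEMATOXYLIN_OD",
    "DAB_OD",
]

# Ruifrok-Johnston H-DAB optical-density vectors (unit norm).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
DAB_OD = np.array([0.269, 0.568, 0.778])
DAB_OD = DAB_OD / np.linalg.norm(DAB_OD)


class PackingError(RuntimeError):
    """Requested cell count cannot be placed at the given minimum separation."""


def _place_hardcore(
    rng: np.random.Generator,
    n: int,
    width_um: float,
    height_um: float,
    d_min_um: float,
    existing: list[tuple[float, float]],
    max_attempts_per_point: int = 1000,
) -> list[tuple[float, float]]:
    """Sequential rejection sampling of a hard-core pattern.

    Proposes uniform points and rejects any closer than ``d_min_um`` to an
    already accepted point (including ``existing``). Raises
    :class:`PackingError` after ``max_attempts_per_point`` consecutive
    rejections rather than silently truncating. A spatial-hash grid of bin
    size ``d_min_um`` keeps each proposal check O(1).
    """
    placed: list[tuple[float, float]] = []
    if d_min_um <= 0:
        return [
            (float(rng.uniform(0.0, width_um)), float(rng.uniform(0.0, height_um)))
            for _ in range(n)
        ]
    d2 = d_min_um * d_min_um
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _conflicts(x: float, y: float) -> bool:
        gx, gy = int(x / d_min_um), int(y / d_min_um)
        for cx in (gx - 1, gx, gx + 1):
            for cy in (gy - 1, gy, gy + 1):
                for px, py in grid.get((cx, cy), ()):
                    if (x - px) ** 2 + (y - py) ** 2 < d2:
                        return True
        return False

    def _insert(x: float, y: float) -> None:
        grid.setdefault((int(x / d_min_um), int(y / d_min_um)), []).append((x, y))

    for px, py in existing:
        _insert(px, py)
    for _ in range(n):
        for _attempt in range(max_attempts_per_point):
            x = float(rng.uniform(0.0, width_um))
            y = float(rng.uniform(0.0, height_um))
            if not _conflicts(x, y):
                placed.append((x, y))
                _insert(x, y)
                break
        else:
            raise PackingError(
                f"could not place point {len(placed) + 1} of {n} after "
                f"{max_attempts_per_point} attempts (d_min={d_min_um} um in "
                f"{width_um}x{height_um} um)"
            )
    return placed


def generate_tissue_roi(
    width_um: float = 150.0,
    height_um: float = 150.0,
    spacing_um_per_px: float = 0.5,
    tumor_density_per_mm2: float = 4000.0,
    other_density_per_mm2: float = 2000.0,
    positivity_fraction: float = 0.3,
    d_min_um: float = 6.0,
    seed: int = 0,
    render: bool = False,
    roi_id: str = "roi",
) -> GroundTruthROI:
    """Generate a ground-truth ROI as a marked hard-core point pattern.

    Cell counts are Poisson with the given intensities (cells/mm^2) over the
    ROI area; positions form a hard-core pattern with minimum separation
    ``d_min_um`` (sequential rejection sampling). Each tumor cell is
    POS_TUMOR independently with probability ``positivity_fraction``, else
    NEG_TUMOR; remaining cells are OTHER.

    Draw order (fixed for reproducibility): tumor count, other count, tumor
    positivity labels, tumor positions, other positions.

    Raises
    ------
    PackingError
        If the sampled count cannot be placed at ``d_min_um``.
    """
    if tumor_density_per_mm2 < 0 or other_density_per_mm2 < 0:
        raise ValueError("densities must be non-negative")
    if not (0.0 <= positivity_fraction <= 1.0):
        raise ValueError("positivity_fraction must lie in [0, 1]")
    if d_min_um < 0:
        raise ValueError("d_min_um must be non-negative")
    if spacing_um_per_px <= 0 or width_um <= 0 or height_um <= 0:
        raise ValueError("geometry parameters must be positive")

    rng = np.random.default_rng(seed)
    area_mm2 = width_um * height_um / 1.0e6
    n_tumor = int(rng.poisson(tumor_density_per_mm2 * area_mm2))
    n_other = int(rng.poisson(other_density_per_mm2 * area_mm2))
    pos_mask = rng.random(n_tumor) < positivity_fraction

    tumor_xy = _place_hardcore(rng, n_tumor, width_um, height_um, d_min_um, [])
    other_xy = _place_hardcore(rng, n_other, width_um, height_um, d_min_um, list(tumor_xy))

    cells = [
        CellPoint(x, y, CellClass.POS_TUMOR if pos else CellClass.NEG_TUMOR, source="truth")
        for (x, y), pos in zip(tumor_xy, pos_mask)
    ]
    cells += [CellPoint(x, y, CellClass.OTHER, source="truth") for x, y in other_xy]

    roi = GroundTruthROI(
        width_um=width_um,
        height_um=height_um,
        spacing_um_per_px=spacing_um_per_px,
        cells=cells,
        seed=seed,
        roi_id=roi_id,
    )
    if render:
        roi.image = render_ihc_image(roi)
    return roi


def render_ihc_image(
    roi: GroundTruthROI,
    nucleus_radius_um: float = 2.8,
    nucleus_peak_od: float = 0.9,
    membrane_radius_um: float = 4.2,
    membrane_width_um: float = 1.2,
    membrane_peak_od: float = 0.7,
) -> np.ndarray:
    """Render an ROI as an H-DAB-like RGB image via Beer-Lambert composition.

    Every cell gets a hematoxylin-toned nucleus (Gaussian-profiled disk of
    optical density ``nucleus_peak_od``); POS_TUMOR cells additionally get a
    DAB-toned membrane ring. Stain densities are composed in optical-density
    space with the Ruifrok-Johnston H and DAB vectors, so color deconvolution
    with the same vectors is a left inverse of this rendering.

    Returns an (H, W, 3) uint8 image on a white background.
    """
    s = roi.spacing_um_per_px
    h_px = max(1, int(round(roi.height_um / s)))
    w_px = max(1, int(round(roi.width_um / s)))
    hem = np.zeros((h_px, w_px), dtype=float)
    dab = np.zeros((h_px, w_px), dtype=float)

    # Pixel-center coordinate grids in micrometers (local patch reuse below).
    r_nuc_px = nucleus_radius_um / s
    r_mem_px = membrane_radius_um / s
    pad = int(math.ceil(max(r_nuc_px, r_mem_px + membrane_width_um / s) + 2))

    for cell in roi.cells:
        # Raster indices of the cell center.
        cj = cell.x_um / s - 0.5
        ci = cell.y_um / s - 0.5
        i0, i1 = max(0, int(ci) - pad), min(h_px, int(ci) + pad + 2)
        j0, j1 = max(0, int(cj) - pad), min(w_px, int(cj) + pad + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        r_px = np.hypot(ii - ci, jj - cj)
        # Smooth-edged nucleus: flat core with a Gaussian shoulder.
        nucleus = nucleus_peak_od * np.exp(-0.5 * (np.maximum(r_px - 0.5 * r_nuc_px, 0.0) / (0.45 * r_nuc_px)) ** 2)
        hem[i0:i1, j0:j1] = np.maximum(hem[i0:i1, j0:j1], nucleus)
        if cell.label is CellClass.POS_TUMOR:
            ring = membrane_peak_od * np.exp(
                -0.5 * ((r_px - r_mem_px) / (0.5 * membrane_width_um / s)) ** 2
            )
            dab[i0:i1, j0:j1] = np.maximum(dab[i0:i1, j0:j1], ring)

    od = hem[..., None] * HEMATOXYLIN_OD + dab[..., None] * DAB_OD
    rgb = np.power(10.0, -od)  # transmitted fraction, white background = 1
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def simulate_reader(
    truth: GroundTruthROI,
    model: ReaderModel,
    seed: int,
    source_id: str = "reader",
) -> AnnotationSet:
    """Simulate one reader's annotation of a ground-truth ROI.

    For each true cell, in generation order: (1) drop it with its class miss
    rate; (2) relabel the survivor by sampling the confusion row of its true
    class; (3) displace it by isotropic Gaussian jitter, clipping to the ROI
    bounds so the miss rate is governed solely by the miss parameter. Then
    spurious points are added as a homogeneous Poisson process with intensity
    ``extra_rate_per_mm2`` and classes drawn from ``extra_class_probs``.

    Random draws per cell occur in the fixed order miss-uniform,
    confusion-categorical, jitter-normal-pair; extras are drawn afterwards
    (count, then per extra: x, y, class).
    """
    rng = np.random.default_rng(seed)
    w, h = truth.width_um, truth.height_um
    x_max = np.nextafter(w, 0.0)
    y_max = np.nextafter(h, 0.0)
    class_index = {c: i for i, c in enumerate(POINT_CLASSES)}

    points: list[CellPoint] = []
    for cell in truth.cells:
        u = rng.random()
        row = class_index[cell.label]
        reported = POINT_CLASSES[rng.choice(3, p=model.confusion[row])]
        dx, dy = rng.normal(0.0, model.jitter_sigma_um or 0.0, size=2) if model.jitter_sigma_um > 0 else (0.0, 0.0)
        if u < model.miss_rate[cell.label]:
            continue
        x = float(np.clip(cell.x_um + dx, 0.0, x_max))
        y = float(np.clip(cell.y_um + dy, 0.0, y_max))
        points.append(CellPoint(x, y, reported, source=source_id))

    n_extra = int(rng.poisson(model.extra_rate_per_mm2 * truth.area_mm2))
    for _ in range(n_extra):
        x = rng.uniform(0.0, w)
        y = rng.uniform(0.0, h)
        cls = POINT_CLASSES[rng.choice(3, p=model.extra_class_probs)]
        points.append(CellPoint(x, y, cls, source=source_id))

    return AnnotationSet(
        roi_id=truth.roi_id,
        source_id=source_id,
        points=points,
        width_um=w,
        height_um=h,
        spacing_um_per_px=truth.spacing_um_per_px,
    )


def expected_recall_under_jitter(sigma_um: float, radius_um: float) -> float:
    """Probability a jittered point stays within the hit radius of its origin.

    With isotropic Gaussian jitter of scale sigma, the displacement is
    Rayleigh(sigma), so P(d <= r) = 1 - exp(-r^2 / (2 sigma^2)). Returns 1
    for sigma = 0.
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if sigma_um == 0:
        return 1.0
    return 1.0 - math.exp(-(radius_um**2) / (2.0 * sigma_um**2))


def round_to_increment(values: np.ndarray | float, increment_pct: float) -> np.ndarray | float:
    """Round to the nearest multiple of ``increment_pct``, half away from zero."""
    v = np.asarray(values, dtype=float)
    out = np.sign(v) * np.floor(np.abs(v) / increment_pct + 0.5) * increment_pct
    return float(out) if np.isscalar(values) else out


def simulate_tps_panel(
    true_tps: Sequence[float],
    n_readers: int = 6,
    reader_sd_pct: float = 8.0,
    increment_pct: float = 5.0,
    seed: int = 0,
    case_ids: Optional[Sequence[str]] = None,
    reader_ids: Optional[Sequence[str]] = None,
) -> TPSPanel:
    """Simulate a panel of visual slide-level TPS estimates.

    Each estimate is ``round(clip(true + N(0, sd), 0, 100))`` to the nearest
    multiple of ``increment_pct`` (half away from zero), emulating visual
    scoring in clinical increments. Draw order: the cases x readers noise
    matrix in one block (row-major), so the panel is deterministic under the
    seed.
    """
    true = np.asarray(true_tps, dtype=float)
    if np.any(true < 0) or np.any(true > 100):
        raise ValueError("true TPS values must lie in [0, 100]")
    if reader_sd_pct < 0:
        raise ValueError("reader_sd_pct must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, reader_sd_pct, size=(len(true), n_readers)) if reader_sd_pct > 0 else np.zeros((len(true), n_readers))
    raw = np.clip(true[:, None] + noise, 0.0, 100.0)
    est = round_to_increment(raw, increment_pct)

    cases = list(case_ids) if case_ids is not None else [f"case_{i:03d}" for i in range(len(true))]
    readers = list(reader_ids) if reader_ids is not None else [f"P{chr(ord('a') + j)}" for j in range(n_readers)]
    df = pd.DataFrame(est, index=pd.Index(cases, name="case_id"), columns=readers)
    return TPSPanel(cases=cases, true_tps=true, estimates=df, increment_pct=increment_pct)
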