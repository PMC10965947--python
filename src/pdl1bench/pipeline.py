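"""End-to-end synthetic reader study: simulate -> annotate -> match -> agree.

``run_pipeline`` reproduces the shape of a two-part PD-L1 benchmarking
study on synthetic data:

* a cell-level study — ROIs annotated by a reader panel and a simulated
  detector, scored with pairwise hit-criterion macro F1 and confusion
  analysis including the background (presence/absence) class;
* a slide-level study — a panel of visual TPS estimates in clinical
  increments plus a count-based detector TPS, scored with ICC(2,1), linear
  weighted kappa at the clinical cutoffs, per-cutoff kappas, majority-vote
  agreement and Bland-Altman limits.

Everything derives from one integer seed through ``numpy`` seed sequences,
so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import __version__
from .agreement import (
    bland_altman,
    icc_2_1,
    kappa_at_cutoff,
    linear_kappa,
    discretize_tps,
    majority_vote_agreement,
)
from .annotation import DetectorParams, detect_nuclei, label_points_by_polygons
from .datatypes import (
    AnnotationSet,
    CellClass,
    CellPoint,
    ConfusionMatrix,
    LabeledPolygon,
    POINT_CLASSES,
    ReaderModel,
)
from .matching import (
    background_disagreement_fraction,
    confusion_from_match,
    match_points,
)
from .metrics import f1_from_confusions, pairwise_f1, summarize_groups
from .synthetic import generate_tissue_roi, render_ihc_image, simulate_tps_panel, simulate_reader

__all__ = ["RunConfig", "run_pipeline", "semiauto_annotation_demo", "default_reader_panel"]


def default_reader_panel(n_readers: int = 6) -> list[tuple[str, ReaderModel]]:
    """A panel of plausible readers with mild parameter spread.

    Error magnitudes are test-bench stand-ins for uncharacterized reader
    behavior, with the dominant confusion NEG_TUMOR <-> OTHER (the most
    prevalent disagreement mode between human readers on PD-L1 IHC).
    """
    panel = []
    for i in range(n_readers):
        f = i / max(1, n_readers - 1)  # 0..1 spread across the panel
        miss = 0.025 + 0.035 * f
        jitter = 1.2 + 0.8 * f
        conf = np.array(
            [
                [0.83 - 0.05 * f, 0.01, 0.16 + 0.05 * f],
                [0.02, 0.90 - 0.04 * f, 0.08 + 0.04 * f],
                [0.12 + 0.04 * f, 0.01, 0.87 - 0.04 * f],
            ]
        )
        model = ReaderModel(
            miss_rate=miss,
            confusion=conf,
            jitter_sigma_um=jitter,
            extra_rate_per_mm2=40.0 + 30.0 * f,
            extra_class_probs=(0.35, 0.1, 0.55),
        )
        panel.append((f"P{i + 1}", model))
    return panel


def default_detector_model() -> ReaderModel:
    """Simulated point-detector noise: tight localization, POS->OTHER bias.

    The detector localizes better than readers (small jitter, few misses)
    but confuses PD-L1 positive tumor cells with 'other' cells more often,
    mirroring the characteristic failure mode of learned PD-L1 detectors on
    macrophage-rich tissue.
    """
    return ReaderModel(
        miss_rate=0.03,
        confusion=np.array(
            [
                [0.900, 0.003, 0.097],
                [0.020, 0.800, 0.180],
                [0.100, 0.020, 0.880],
            ]
        ),
        jitter_sigma_um=0.8,
        extra_rate_per_mm2=60.0,
        extra_class_probs=(0.3, 0.1, 0.6),
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic study run."""

    seed: int = 0
    # cell-level study
    n_cases_cell: int = 8
    rois_per_case: int = 4
    roi_width_um: float = 150.0
    roi_height_um: float = 150.0
    spacing_um_per_px: float = 0.5
    tumor_density_per_mm2: float = 4000.0
    other_density_per_mm2: float = 2000.0
    d_min_um: float = 6.0
    n_readers_cell: int = 3
    # slide-level study
    n_cases_tps: int = 100
    n_readers_tps: int = 6
    reader_sd_pct: float = 8.0
    increment_pct: float = 5.0
    ai_tumor_cells_per_case: int = 500
    ai_other_cells_per_case: int = 250
    # analysis
    radius_um: float = 8.0
    metric_mode: str = "per_case"
    cutoffs: tuple[float, float] = (1.0, 50.0)
    matching_mode: str = "one-to-one"
    tie_rule: str = "drop"
    ai_id: str = "AI"
    noiseless: bool = False  # degenerate configuration: perfect readers and detector
    include_annotation_demo: bool = True

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        d.update(overrides)
        if "cutoffs" in d:
            d["cutoffs"] = tuple(d["cutoffs"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sample_true_tps(rng: np.random.Generator, n: int) -> np.ndarray:
    """Clinically shaped true-TPS mixture spanning the three categories.

    Roughly a third of cases per clinical band, with continuous values
    inside each band — a diverse panel rather than an estimate of any real
    cohort's distribution.
    """
    u = rng.random(n)
    t = np.empty(n)
    low = u < 0.30
    mid = (u >= 0.30) & (u < 0.65)
    high = u >= 0.65
    t[low] = rng.uniform(0.0, 1.0, low.sum())
    t[mid] = rng.uniform(1.0, 50.0, mid.sum())
    t[high] = rng.uniform(50.0, 100.0, high.sum())
    return t


def semiauto_annotation_demo(
    seed: int = 0,
    n_band_cells: int = 20,
    spacing_um_per_px: float = 0.5,
    detector_params: DetectorParams = DetectorParams(),
) -> dict:
    """Run the two-step semi-automatic annotation on a rendered synthetic ROI.

    Builds an ROI with three vertical bands of homogeneous cell type
    (positive tumor, negative tumor, other) and the matching free-hand
    polygons, renders it as an H-DAB image, detects nuclei with the
    classical stand-in, transfers labels from the polygons, and scores the
    result against the ground truth under the hit criterion.

    Returns a dict with the ROI, the labeled annotation set, and summary
    numbers (detection F1, label accuracy, mean localization error).
    """
    width = 180.0
    height = 120.0
    band = width / 3.0
    margin = 8.0
    rng = np.random.default_rng(seed)

    cells: list[CellPoint] = []
    band_classes = (CellClass.POS_TUMOR, CellClass.NEG_TUMOR, CellClass.OTHER)
    for bi, cls in enumerate(band_classes):
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_band_cells and attempts < 20000:
            x = rng.uniform(bi * band + margin, (bi + 1) * band - margin)
            y = rng.uniform(margin, height - margin)
            if all((x - px) ** 2 + (y - py) ** 2 >= 10.0**2 for px, py in placed):
                placed.append((x, y))
            attempts += 1
        cells += [CellPoint(x, y, cls, source="truth") for x, y in placed]

    from .datatypes import GroundTruthROI

    roi = GroundTruthROI(
        width_um=width,
        height_um=height,
        spacing_um_per_px=spacing_um_per_px,
        cells=cells,
        seed=seed,
        roi_id="semiauto_demo",
    )
    roi.image = render_ihc_image(roi)

    polygons = [
        LabeledPolygon(
            (
                (bi * band, 0.0),
                ((bi + 1) * band, 0.0),
                ((bi + 1) * band, height),
                (bi * band, height),
            ),
            cls,
            roi_id=roi.roi_id,
        )
        for bi, cls in enumerate(band_classes)
    ]

    detections = detect_nuclei(roi.image, spacing_um_per_px, params=detector_params)
    labeled = label_points_by_polygons(
        detections,
        polygons,
        roi_id=roi.roi_id,
        width_um=width,
        height_um=height,
        spacing_um_per_px=spacing_um_per_px,
    )

    truth_set = roi.as_annotation_set()
    m = match_points(truth_set, labeled, radius_um=8.0)
    conf = confusion_from_match(m)
    report = f1_from_confusions([conf])
    n_truth = len(truth_set)
    correct = sum(1 for p in m.pairs if p.reference.label == p.prediction.label)
    mean_loc_err = float(np.mean([p.distance_um for p in m.pairs])) if m.pairs else float("nan")
    within_3um_correct = sum(
        1
        for p in m.pairs
        if p.reference.label == p.prediction.label and p.distance_um <= 3.0
    )
    return {
        "roi": roi,
        "annotation_set": labeled,
        "match": m,
        "macro_f1": report.macro_f1,
        "n_truth": n_truth,
        "n_detected": len(labeled),
        "n_matched": len(m.pairs),
        "n_correct_label": correct,
        "recovered_fraction": within_3um_correct / n_truth if n_truth else float("nan"),
        "mean_localization_error_um": mean_loc_err,
    }


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run directory."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True), encoding="utf-8")


def _nan_to_none(x):
    if isinstance(x, float) and not np.isfinite(x):
        return None
    if isinstance(x, dict):
        return {k: _nan_to_none(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_nan_to_none(v) for v in x]
    return x


def run_pipeline(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full synthetic study; write reports and provenance to disk.

    Returns the in-memory results dict (same content as the JSON reports).
    Any stage error aborts with the stage name; outputs of completed stages
    stay in the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    root_ss = np.random.SeedSequence(config.seed)
    ss_cell, ss_tps, ss_demo = root_ss.spawn(3)

    results: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate-cell"
        if config.noiseless:
            panel = [(f"P{i + 1}", ReaderModel.noiseless()) for i in range(config.n_readers_cell)]
            detector = ReaderModel.noiseless()
        else:
            panel = default_reader_panel(config.n_readers_cell)
            detector = default_detector_model()
        sources = [rid for rid, _ in panel] + [config.ai_id]

        sets: dict[str, dict[str, AnnotationSet]] = {s: {} for s in sources}
        case_of: dict[str, str] = {}
        roi_seeds = ss_cell.spawn(config.n_cases_cell)
        n_cells_total = 0
        for ci in range(config.n_cases_cell):
            case_id = f"case_{ci:03d}"
            case_rng = np.random.default_rng(roi_seeds[ci])
            positivity = float(case_rng.uniform(0.05, 0.95))
            for ri in range(config.rois_per_case):
                roi_id = f"{case_id}_roi{ri}"
                base = int(case_rng.integers(0, 2**31 - 1))
                roi = generate_tissue_roi(
                    width_um=config.roi_width_um,
                    height_um=config.roi_height_um,
                    spacing_um_per_px=config.spacing_um_per_px,
                    tumor_density_per_mm2=config.tumor_density_per_mm2,
                    other_density_per_mm2=config.other_density_per_mm2,
                    positivity_fraction=positivity,
                    d_min_um=config.d_min_um,
                    seed=base,
                    roi_id=roi_id,
                )
                n_cells_total += len(roi.cells)
                case_of[roi_id] = case_id
                for k, (rid, model) in enumerate(panel):
                    sets[rid][roi_id] = simulate_reader(roi, model, seed=base + 1 + k, source_id=rid)
                sets[config.ai_id][roi_id] = simulate_reader(
                    roi, detector, seed=base + 1 + len(panel), source_id=config.ai_id
                )
        log(stage, f"{config.n_cases_cell} cases x {config.rois_per_case} ROIs, "
                   f"{n_cells_total} true cells, sources={sources}")

        # ------------------------------------------------------------------
        stage = "metrics-cell"
        pw = pairwise_f1(sets, radius_um=config.radius_um, mode=config.metric_mode, case_of=case_of)
        reader_ids = [rid for rid, _ in panel]
        rr_vals = pw.pair_values(reader_ids)
        ra_vals = pw.pair_values(reader_ids, [config.ai_id])
        rr_summary = summarize_groups(rr_vals)
        ra_summary = summarize_groups(ra_vals)

        # pooled confusions per pair, for the background-disagreement stat
        def pooled_conf(a: str, b: str) -> ConfusionMatrix:
            confs = []
            for roi_id in sorted(set(sets[a]) & set(sets[b])):
                m = match_points(sets[a][roi_id], sets[b][roi_id], radius_um=config.radius_um,
                                 mode=config.matching_mode)
                confs.append(confusion_from_match(m))
            total = confs[0]
            for c in confs[1:]:
                total = total + c
            return total

        def _finite_mean(vals: list[float]) -> float:
            finite = [v for v in vals if np.isfinite(v)]
            return float(np.mean(finite)) if finite else float("nan")

        bg_rr = [background_disagreement_fraction(pooled_conf(a, b))
                 for a, b in combinations(reader_ids, 2)]
        bg_ra = [background_disagreement_fraction(pooled_conf(r, config.ai_id))
                 for r in reader_ids]
        total_conf = pooled_conf(reader_ids[0], reader_ids[1])

        cell_results = {
            "pairwise_macro_f1": {a: {b: _nan_to_none(float(pw.values.loc[a, b]))
                                      for b in sources} for a in sources},
            "mode": pw.mode,
            "reader_reader_f1": rr_summary.to_dict(),
            "reader_ai_f1": ra_summary.to_dict(),
            "background_disagreement": {
                "reader_reader_mean": _nan_to_none(_finite_mean(bg_rr)),
                "reader_ai_mean": _nan_to_none(_finite_mean(bg_ra)),
            },
        }
        results["cell_level"] = cell_results
        pw.values.to_csv(out / "pairwise_f1.csv")
        total_conf.to_dataframe().to_csv(out / "confusion_first_reader_pair.csv")
        _json_dump(_nan_to_none(cell_results), out / "f1_report.json")
        log(stage, f"mean reader-reader F1 {rr_summary.mean:.3f}, "
                   f"mean reader-AI F1 {ra_summary.mean:.3f}")

        # ------------------------------------------------------------------
        stage = "simulate-tps"
        tps_rng = np.random.default_rng(ss_tps)
        true_tps = _sample_true_tps(tps_rng, config.n_cases_tps)
        panel_seed = int(tps_rng.integers(0, 2**31 - 1))
        tps_panel = simulate_tps_panel(
            true_tps,
            n_readers=config.n_readers_tps,
            reader_sd_pct=0.0 if config.noiseless else config.reader_sd_pct,
            increment_pct=config.increment_pct,
            seed=panel_seed,
        )
        table = tps_panel.estimates.copy()

        # Detector TPS from simulated counts: each true cell's class is
        # re-drawn through the detector's confusion row; cells read as
        # 'other' leave the TPS denominator.
        ai_tps = np.empty(config.n_cases_tps)
        conf_m = np.eye(3) if config.noiseless else default_detector_model().confusion
        i_neg, i_pos = POINT_CLASSES.index(CellClass.NEG_TUMOR), POINT_CLASSES.index(CellClass.POS_TUMOR)
        for i, t in enumerate(true_tps):
            n_pos_true = tps_rng.binomial(config.ai_tumor_cells_per_case, t / 100.0)
            n_neg_true = config.ai_tumor_cells_per_case - n_pos_true
            pos_out = tps_rng.multinomial(n_pos_true, conf_m[i_pos])
            neg_out = tps_rng.multinomial(n_neg_true, conf_m[i_neg])
            n_pos = int(pos_out[i_pos] + neg_out[i_pos])
            n_neg = int(pos_out[i_neg] + neg_out[i_neg])
            ai_tps[i] = 100.0 * n_pos / (n_pos + n_neg) if n_pos + n_neg else 0.0
        if config.noiseless:
            ai_tps = true_tps.copy()
            table.loc[:, :] = np.tile(true_tps[:, None], (1, config.n_readers_tps))
        table[config.ai_id] = ai_tps
        log(stage, f"{config.n_cases_tps} cases, {config.n_readers_tps} readers + AI")

        # ------------------------------------------------------------------
        stage = "agreement"
        reader_cols = [c for c in table.columns if c != config.ai_id]
        icc_readers = icc_2_1(table[reader_cols])
        icc_all = icc_2_1(table)
        icc_ra_pairs = [icc_2_1(table[[r, config.ai_id]]).value for r in reader_cols]

        codes = {c: [discretize_tps(v) for v in table[c]] for c in table.columns}
        kappa_rr = [linear_kappa(codes[a], codes[b]) for a, b in combinations(reader_cols, 2)]
        kappa_ra = [linear_kappa(codes[r], codes[config.ai_id]) for r in reader_cols]
        kap_rr_summary = summarize_groups(kappa_rr)
        kap_ra_summary = summarize_groups(kappa_ra)

        per_cutoff = {}
        for cutoff in config.cutoffs:
            rr = [kappa_at_cutoff(table[a], table[b], cutoff) for a, b in combinations(reader_cols, 2)]
            ra = [kappa_at_cutoff(table[r], table[config.ai_id], cutoff) for r in reader_cols]
            mv = {
                src: majority_vote_agreement(table, src, cutoff, readers=reader_cols,
                                             tie_rule=config.tie_rule).to_dict()
                for src in list(reader_cols) + [config.ai_id]
            }
            per_cutoff[f"{cutoff:g}"] = {
                "reader_reader_mean": _nan_to_none(float(np.nanmean(rr))),
                "reader_ai_mean": _nan_to_none(float(np.nanmean(ra))),
                "majority_vote": _nan_to_none(mv),
            }

        median_reader = table[reader_cols].median(axis=1)
        ba = bland_altman(table[config.ai_id], median_reader)

        agreement_results = {
            "icc_readers": icc_readers.to_dict(),
            "icc_readers_plus_ai": icc_all.to_dict(),
            "icc_reader_ai_pairs_mean": _nan_to_none(float(np.nanmean(icc_ra_pairs))),
            "linear_kappa": {
                "reader_reader": kap_rr_summary.to_dict(),
                "reader_ai": kap_ra_summary.to_dict(),
            },
            "per_cutoff": per_cutoff,
            "bland_altman_ai_minus_median_reader": ba.to_dict(),
        }
        results["slide_level"] = agreement_results
        _json_dump(_nan_to_none(agreement_results), out / "agreement.json")
        table.to_csv(out / "tps_table.csv")
        log(stage, f"ICC(2,1) readers {icc_readers.value:.3f}; "
                   f"mean linear kappa RR {kap_rr_summary.mean:.3f} / RA {kap_ra_summary.mean:.3f}; "
                   f"BA mean diff {ba.mean_diff:.2f}")

        # ------------------------------------------------------------------
        if config.include_annotation_demo:
            stage = "annotation-demo"
            demo_seed = int(np.random.default_rng(ss_demo).integers(0, 2**31 - 1))
            demo = semiauto_annotation_demo(seed=demo_seed, spacing_um_per_px=config.spacing_um_per_px)
            results["semiauto_annotation"] = {
                "macro_f1": _nan_to_none(demo["macro_f1"]),
                "n_truth": demo["n_truth"],
                "n_detected": demo["n_detected"],
                "recovered_fraction": _nan_to_none(demo["recovered_fraction"]),
                "mean_localization_error_um": _nan_to_none(demo["mean_localization_error_um"]),
            }
            _json_dump(results["semiauto_annotation"], out / "semiauto_annotation.json")
            log(stage, f"recovered {demo['recovered_fraction']:.1%} of {demo['n_truth']} cells, "
                       f"mean loc error {demo['mean_localization_error_um']:.2f} um")

        # ------------------------------------------------------------------
        stage = "provenance"
        provenance = {
            "config": {**asdict(config), "cutoffs": list(config.cutoffs)},
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
            "flags": {
                "matching_mode": config.matching_mode,
                "metric_mode": config.metric_mode,
                "majority_tie_rule": config.tie_rule,
            },
        }
        _json_dump(provenance, out / "provenance.json")
        (out / "log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    except Exception as exc:
        (out / "log.txt").write_text("\n".join(log_lines) + f"\n[FAILED at {stage}] {exc}\n",
                                     encoding="utf-8")
        raise PipelineError(stage, exc) from exc

    return results
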