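"""File formats: annotation CSV/GeoJSON, ASAP XML, polygons, ROIs, TPS tables.

The annotation CSV dialect has a required header
``roi_id,reader_id,x_um,y_um,class,confidence`` (confidence may be empty),
UTF-8. GeoJSON annotation files are FeatureCollections of Point features
with properties ``class`` and ``source``. The optional ASAP XML reader
understands ``<Annotation Type="Dot"|"Polygon">`` elements with
``<Coordinate X Y>`` children; ASAP coordinates are pixels and are
converted to micrometers with the provided spacing.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .datatypes import (
    AnnotationSet,
    CellClass,
    CellPoint,
    GroundTruthROI,
    LabeledPolygon,
    TPSRecord,
    parse_cell_class,
)

__all__ = [
    "ANNOTATION_CSV_COLUMNS",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_annotations_geojson",
    "read_annotations_geojson",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "read_asap_xml",
    "write_roi",
    "read_roi",
    "write_tps_csv",
    "read_tps_csv",
    "tps_records_to_table",
]

ANNOTATION_CSV_COLUMNS = ["roi_id", "reader_id", "x_um", "y_um", "class", "confidence"]


def write_annotations_csv(
    sets: Union[AnnotationSet, Sequence[AnnotationSet]], path: Union[str, Path]
) -> None:
    """Write one or more annotation sets to the CSV dialect."""
    sets = [sets] if isinstance(sets, AnnotationSet) else list(sets)
    rows = []
    for s in sets:
        s.require_labeled()
        for p in s.points:
            rows.append(
                {
                    "roi_id": s.roi_id,
                    "reader_id": s.source_id,
                    "x_um": repr(float(p.x_um)),
                    "y_um": repr(float(p.y_um)),
                    "class": p.label.value,
                    "confidence": "" if p.confidence is None else repr(float(p.confidence)),
                }
            )
    pd.DataFrame(rows, columns=ANNOTATION_CSV_COLUMNS).to_csv(path, index=False)


def read_annotations_csv(
    path: Union[str, Path],
    width_um: Optional[float] = None,
    height_um: Optional[float] = None,
    spacing_um_per_px: Optional[float] = None,
) -> list[AnnotationSet]:
    """Read annotation sets from CSV, one set per (roi_id, reader_id) pair.

    Malformed rows raise with the 1-based data line number; unknown class
    labels are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    groups: dict[tuple[str, str], list[CellPoint]] = {}
    order: list[tuple[str, str]] = []
    for line_no, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            x = float(row["x_um"])
            y = float(row["y_um"])
            label = parse_cell_class(row["class"])
            conf_raw = row.get("confidence", "")
            conf = float(conf_raw) if str(conf_raw).strip() != "" else None
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at data line {line_no}: {exc}") from exc
        key = (str(row["roi_id"]), str(row["reader_id"]))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(CellPoint(x, y, label, confidence=conf, source=key[1]))
    return [
        AnnotationSet(
            roi_id=roi,
            source_id=reader,
            points=groups[(roi, reader)],
            width_um=width_um,
            height_um=height_um,
            spacing_um_per_px=spacing_um_per_px,
        )
        for roi, reader in order
    ]


def write_annotations_geojson(aset: AnnotationSet, path: Union[str, Path]) -> None:
    """Write one annotation set as a GeoJSON FeatureCollection of Points."""
    aset.require_labeled()
    features = []
    for p in aset.points:
        props = {"class": p.label.value, "source": aset.source_id, "roi_id": aset.roi_id}
        if p.confidence is not None:
            props["confidence"] = p.confidence
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x_um, p.y_um]},
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_annotations_geojson(
    path: Union[str, Path],
    width_um: Optional[float] = None,
    height_um: Optional[float] = None,
    spacing_um_per_px: Optional[float] = None,
) -> AnnotationSet:
    """Read a Point FeatureCollection; errors name the offending feature index."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    points: list[CellPoint] = []
    roi_id, source_id = "roi", "unknown"
    for idx, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {idx} is not a Point")
        props = feat.get("properties") or {}
        if "class" not in props:
            raise ValueError(f"{path}: feature {idx} missing 'class' property")
        try:
            label = parse_cell_class(props["class"])
        except ValueError as exc:
            raise ValueError(f"{path}: feature {idx}: {exc}") from exc
        x, y = geom["coordinates"][:2]
        roi_id = str(props.get("roi_id", roi_id))
        source_id = str(props.get("source", source_id))
        points.append(
            CellPoint(float(x), float(y), label, confidence=props.get("confidence"), source=source_id)
        )
    return AnnotationSet(
        roi_id=roi_id,
        source_id=source_id,
        points=points,
        width_um=width_um,
        height_um=height_um,
        spacing_um_per_px=spacing_um_per_px,
    )


def write_polygons_geojson(polygons: Sequence[LabeledPolygon], path: Union[str, Path]) -> None:
    features = []
    for poly in polygons:
        ring = [list(v) for v in poly.vertices]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"class": poly.label.value, "roi_id": poly.roi_id},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
        encoding="utf-8",
    )


def read_polygons_geojson(path: Union[str, Path]) -> list[LabeledPolygon]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    polys: list[LabeledPolygon] = []
    for idx, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"{path}: feature {idx} is not a Polygon")
        props = feat.get("properties") or {}
        if "class" not in props:
            raise ValueError(f"{path}: feature {idx} missing 'class' property")
        label = parse_cell_class(props["class"])
        ring = geom["coordinates"][0]
        verts = [tuple(map(float, v)) for v in ring]
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        polys.append(
            LabeledPolygon(tuple(verts), label, roi_id=str(props.get("roi_id", "roi")))
        )
    return polys


def read_asap_xml(
    path: Union[str, Path],
    spacing_um_per_px: float,
    class_map: Optional[dict[str, CellClass]] = None,
) -> tuple[list[CellPoint], list[LabeledPolygon]]:
    """Read ASAP XML annotations (Dot and Polygon), converting px to um.

    ASAP stores coordinates in pixels; they are multiplied by
    ``spacing_um_per_px``. The annotation's ``PartOfGroup`` attribute is
    mapped to a cell class through ``class_map`` (falling back to direct
    label parsing; dots without a resolvable class get ``label=None``).
    """
    if spacing_um_per_px <= 0:
        raise ValueError("spacing must be positive")
    root = ET.parse(str(path)).getroot()
    class_map = class_map or {}
    dots: list[CellPoint] = []
    polys: list[LabeledPolygon] = []
    for ann in root.iter("Annotation"):
        ann_type = ann.get("Type", "")
        group = ann.get("PartOfGroup", ann.get("Name", ""))
        label: Optional[CellClass]
        if group in class_map:
            label = class_map[group]
        else:
            try:
                label = parse_cell_class(group)
            except ValueError:
                label = None
        coords = [
            (float(c.get("X")) * spacing_um_per_px, float(c.get("Y")) * spacing_um_per_px)
            for c in sorted(ann.iter("Coordinate"), key=lambda c: int(c.get("Order", 0)))
        ]
        if ann_type == "Dot":
            for x, y in coords:
                dots.append(CellPoint(x, y, label, source=ann.get("Name")))
        elif ann_type == "Polygon":
            if label is None:
                raise ValueError(
                    f"{path}: polygon {ann.get('Name')!r} has unmapped group {group!r}"
                )
            polys.append(LabeledPolygon(tuple(coords), label))
    return dots, polys


def write_roi(roi: GroundTruthROI, out_dir: Union[str, Path], stem: str = "roi") -> dict[str, Path]:
    """Write a ground-truth ROI: PNG image (if rendered), GeoJSON points, sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if roi.image is not None:
        import imageio.v3 as iio

        img_path = out / f"{stem}.png"
        iio.imwrite(img_path, roi.image)
        paths["image"] = img_path
    gj_path = out / f"{stem}_points.geojson"
    write_annotations_geojson(roi.as_annotation_set("truth"), gj_path)
    paths["points"] = gj_path
    sidecar = {
        "width_um": roi.width_um,
        "height_um": roi.height_um,
        "spacing_um_per_px": roi.spacing_um_per_px,
        "seed": roi.seed,
        "roi_id": roi.roi_id,
    }
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    paths["meta"] = meta_path
    return paths


def read_roi(out_dir: Union[str, Path], stem: str = "roi") -> GroundTruthROI:
    """Read back a ROI written by :func:`write_roi`."""
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}_meta.json").read_text(encoding="utf-8"))
    aset = read_annotations_geojson(out / f"{stem}_points.geojson")
    image = None
    img_path = out / f"{stem}.png"
    if img_path.exists():
        import imageio.v3 as iio

        image = iio.imread(img_path)
    return GroundTruthROI(
        width_um=meta["width_um"],
        height_um=meta["height_um"],
        spacing_um_per_px=meta["spacing_um_per_px"],
        cells=list(aset.points),
        seed=meta["seed"],
        image=image,
        roi_id=meta.get("roi_id", stem),
    )


def write_tps_csv(records: Sequence[TPSRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "case_id": r.case_id,
            "source_id": r.source_id,
            "tps_pct": r.tps_pct,
            "n_pos": "" if r.n_pos_tumor is None else r.n_pos_tumor,
            "n_neg": "" if r.n_neg_tumor is None else r.n_neg_tumor,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["case_id", "source_id", "tps_pct", "n_pos", "n_neg"]).to_csv(
        path, index=False
    )


def read_tps_csv(path: Union[str, Path]) -> list[TPSRecord]:
    df = pd.read_csv(path, dtype={"case_id": str, "source_id": str})
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            n_pos = None if pd.isna(row.n_pos) else int(row.n_pos)
            n_neg = None if pd.isna(row.n_neg) else int(row.n_neg)
            records.append(
                TPSRecord(
                    case_id=str(row.case_id),
                    source_id=str(row.source_id),
                    tps_pct=float(row.tps_pct),
                    n_pos_tumor=n_pos,
                    n_neg_tumor=n_neg,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at data line {line_no}: {exc}") from exc
    return records


def tps_records_to_table(records: Sequence[TPSRecord]) -> pd.DataFrame:
    """Pivot TPS records into a cases x sources table of percentages."""
    df = pd.DataFrame(
        [(r.case_id, r.source_id, r.tps_pct) for r in records],
        columns=["case_id", "source_id", "tps_pct"],
    )
    return df.pivot(index="case_id", columns="source_id", values="tps_pct")
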