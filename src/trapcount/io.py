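"""Readers and writers for annotations, detections, counts and pipeline config.

Annotations travel as Pascal-VOC-style XML (one file per image, corner
coordinates xmin/ymin/xmax/ymax) or COCO-style JSON (one file per
dataset, ``bbox = [x, y, width, height]``).  Whatever the source
dialect, coordinates are normalized on read to the package-wide 0-based
half-open convention; classic VOC files with 1-based inclusive corners
are converted with ``origin="one"`` (xmin-1, ymin-1; xmax/ymax already
act as exclusive bounds after the shift).  Detections are exchanged in
the COCO results convention (bbox + score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from lxml import etree

from .geometry import BoundingBox, Detection, DEFAULT_LABEL

__all__ = [
    "AnnotationRecord",
    "AnnotationError",
    "PipelineConfig",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
    "read_counts_csv",
    "write_counts_csv",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class AnnotationRecord:
    """Ground-truth annotations for one image."""

    image_id: str
    width: int
    height: int
    boxes: tuple[tuple[str, BoundingBox], ...]

    def __init__(self, image_id, width, height, boxes):
        object.__setattr__(self, "image_id", str(image_id))
        object.__setattr__(self, "width", int(width))
        object.__setattr__(self, "height", int(height))
        object.__setattr__(self, "boxes", tuple((str(l), b) for l, b in boxes))
        for label, b in self.boxes:
            if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
                raise AnnotationError(
                    f"{self.image_id}: box {b.as_tuple()} outside image "
                    f"{self.width} x {self.height}"
                )

    @property
    def bounding_boxes(self) -> list[BoundingBox]:
        return [b for _, b in self.boxes]


# ---------------------------------------------------------------------------
# Pascal-VOC XML
# ---------------------------------------------------------------------------


def _record_to_voc_xml(rec: AnnotationRecord) -> etree._Element:
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = rec.image_id
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(rec.width)
    etree.SubElement(size, "height").text = str(rec.height)
    etree.SubElement(size, "depth").text = "3"
    for label, b in rec.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        bnd = etree.SubElement(obj, "bndbox")
        for tag, v in zip(("xmin", "ymin", "xmax", "ymax"), b.as_tuple()):
            etree.SubElement(bnd, tag).text = repr(v)
    return root


def _voc_xml_to_record(path: Path, origin: str) -> AnnotationRecord:
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as e:
        raise AnnotationError(f"{path}: not well-formed XML ({e})") from e
    try:
        image_id = root.findtext("filename") or path.stem
        size = root.find("size")
        width = int(float(size.findtext("width")))
        height = int(float(size.findtext("height")))
    except (AttributeError, TypeError, ValueError) as e:
        raise AnnotationError(f"{path}: missing or invalid size/filename") from e
    shift = 1.0 if origin == "one" else 0.0
    boxes = []
    for k, obj in enumerate(root.findall("object")):
        label = obj.findtext("name") or DEFAULT_LABEL
        bnd = obj.find("bndbox")
        try:
            coords = [float(bnd.findtext(t)) for t in ("xmin", "ymin", "xmax", "ymax")]
        except (AttributeError, TypeError, ValueError) as e:
            raise AnnotationError(f"{path}: object {k}: bad bndbox") from e
        boxes.append(
            (label, BoundingBox(coords[0] - shift, coords[1] - shift, coords[2], coords[3]))
        )
    return AnnotationRecord(image_id=image_id, width=width, height=height, boxes=boxes)


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------


def _records_to_coco(records: Sequence[AnnotationRecord]) -> dict:
    labels = sorted({l for rec in records for l, _ in rec.boxes}) or [DEFAULT_LABEL]
    cat_id = {name: i + 1 for i, name in enumerate(labels)}
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(records, start=1):
        images.append(
            {"id": img_id, "file_name": rec.image_id, "width": rec.width, "height": rec.height}
        )
        for label, b in rec.boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[label],
                    "bbox": [b.xmin, b.ymin, b.width, b.height],
                    "area": b.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in cat_id.items()],
    }


def _coco_to_records(data: dict, path: Path) -> list[AnnotationRecord]:
    try:
        cats = {c["id"]: c["name"] for c in data.get("categories", [])}
        by_image: dict[int, list] = {img["id"]: [] for img in data["images"]}
        for ann in data.get("annotations", []):
            x, y, w, h = ann["bbox"]
            by_image[ann["image_id"]].append(
                (cats.get(ann.get("category_id"), DEFAULT_LABEL), BoundingBox(x, y, x + w, y + h))
            )
        return [
            AnnotationRecord(
                image_id=img["file_name"],
                width=img["width"],
                height=img["height"],
                boxes=by_image[img["id"]],
            )
            for img in data["images"]
        ]
    except (KeyError, TypeError, ValueError) as e:
        raise AnnotationError(f"{path}: invalid COCO annotation structure ({e})") from e


# ---------------------------------------------------------------------------
# public annotation API
# ---------------------------------------------------------------------------


def write_annotations(
    records: Sequence[AnnotationRecord], path: str | Path, fmt: str = "voc"
) -> None:
    """Write annotations: ``fmt="voc"`` to a directory of per-image XML
    files, ``fmt="coco"`` to a single JSON file."""
    path = Path(path)
    if fmt == "voc":
        path.mkdir(parents=True, exist_ok=True)
        for rec in records:
            stem = Path(rec.image_id).stem
            tree = etree.ElementTree(_record_to_voc_xml(rec))
            tree.write(
                str(path / f"{stem}.xml"), pretty_print=True, encoding="utf-8"
            )
    elif fmt == "coco":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(_records_to_coco(records), indent=1))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def read_annotations(
    path: str | Path, fmt: str = "voc", origin: str = "zero"
) -> list[AnnotationRecord]:
    """Read annotations from a VOC XML file/directory or a COCO JSON file.

    ``origin="one"`` declares classic 1-based inclusive VOC coordinates,
    which are shifted to the 0-based half-open convention on read.
    """
    path = Path(path)
    if origin not in ("zero", "one"):
        raise ValueError("origin must be 'zero' or 'one'")
    if fmt == "voc":
        files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
        if not files:
            raise AnnotationError(f"{path}: no XML annotation files found")
        return [_voc_xml_to_record(f, origin) for f in files]
    if fmt == "coco":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise AnnotationError(f"{path}: not valid JSON ({e})") from e
        return _coco_to_records(data, path)
    raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# detections (COCO results convention)
# ---------------------------------------------------------------------------


def write_detections(dets_by_image: dict[str, Sequence[Detection]], path: str | Path) -> None:
    """Write detections as a COCO-style results JSON list
    (``image_id``, ``bbox=[x, y, w, h]``, ``score``, ``category``)."""
    rows = [
        {
            "image_id": image_id,
            "category": d.label,
            "bbox": [d.box.xmin, d.box.ymin, d.box.width, d.box.height],
            "score": d.score,
        }
        for image_id, dets in dets_by_image.items()
        for d in dets
    ]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_detections(path: str | Path) -> dict[str, list[Detection]]:
    """Read a COCO-style results JSON list into per-image detection lists."""
    data = json.loads(Path(path).read_text())
    out: dict[str, list[Detection]] = {}
    for row in data:
        x, y, w, h = row["bbox"]
        out.setdefault(str(row["image_id"]), []).append(
            Detection(
                BoundingBox(x, y, x + w, y + h),
                float(row["score"]),
                str(row.get("category", DEFAULT_LABEL)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-trap counts
# ---------------------------------------------------------------------------


def write_counts_csv(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"trap_id": list(counts), "count": list(counts.values())}
    ).to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    return dict(zip(df["trap_id"].astype(str), df["count"].astype(int)))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved configuration of one counting run.

    Defaults are the standard operating point of the pipeline on
    full-resolution traps: a 500 px window (the alternative condition
    uses 1000) with 100 px of overlap.  ``score_threshold`` may be the
    string ``"calibrate"`` to request calibration on a held-out subset.
    """

    window_size: int = 500
    overlap: int = 100
    nms_iou: float = 0.5
    edge_tolerance: float = 1.0
    score_threshold: float | str = 0.5
    detector: str = "blob"
    detector_params: dict = field(default_factory=dict)
    iou_thresholds_for_ap: tuple[float, ...] = (0.3, 0.5)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = cls(**data)
        if isinstance(cfg.iou_thresholds_for_ap, list):
            cfg.iou_thresholds_for_ap = tuple(cfg.iou_thresholds_for_ap)
        return cfg

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        data["iou_thresholds_for_ap"] = list(self.iou_thresholds_for_ap)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=1))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
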