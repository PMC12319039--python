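"""Detections, bounding boxes, and the two on-disk detection dialects.

Boxes use a 0-based, half-open pixel convention: a box covers the pixel set
``[x_min, x_max) x [y_min, y_max)``, so ``width = x_max - x_min`` and areas and
intersections are integer-exact on integer boxes.  The flat-CSV dialect is
defined by this package (header below); the JSON dialect is a COCO-style
subset with ``[x, y, w, h]`` boxes.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

CLASS_NAMES = {1: "one", 2: "two", 3: "three", 4: "four"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}
VALID_CLASSES = frozenset(CLASS_NAMES)
VIEWS = ("front", "rear")

CSV_HEADER = ["plant_id", "view", "x_min", "y_min", "x_max", "y_max", "class", "confidence"]


class DetectionError(ValueError):
    """Malformed detection record (bad class, box, or confidence)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, half-open pixel coordinates, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        for v in (self.x_min, self.y_min, self.x_max, self.y_max):
            if not math.isfinite(v):
                raise DetectionError(f"non-finite box coordinate: {self}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise DetectionError(f"degenerate box (needs x_max>x_min, y_max>y_min): {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        return cls(x, y, x + w, y + h)


@dataclass(frozen=True)
class Detection:
    """One detected pod: box, seed-count class, confidence, and view tag.

    ``source_id`` carries the ground-truth pod identity when the detection
    comes from a synthetic-scene oracle; file-ingested detections leave it None.
    """

    box: BoundingBox
    pod_class: int
    confidence: float
    view: str
    source_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pod_class not in VALID_CLASSES:
            raise DetectionError(f"pod class must be in {sorted(VALID_CLASSES)}, got {self.pod_class}")
        if not (0.0 <= self.confidence <= 1.0) or not math.isfinite(self.confidence):
            raise DetectionError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.view not in VIEWS:
            raise DetectionError(f"view must be one of {VIEWS}, got {self.view!r}")


@dataclass
class PodSet:
    """Ordered detections of one view of one plant."""

    plant_id: str
    view: str
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise DetectionError(f"view must be one of {VIEWS}, got {self.view!r}")
        for d in self.detections:
            if d.view != self.view:
                raise DetectionError(f"detection view {d.view!r} != pod-set view {self.view!r}")

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def __getitem__(self, i: int) -> Detection:
        return self.detections[i]

    def class_histogram(self) -> dict[int, int]:
        counts = {c: 0 for c in sorted(VALID_CLASSES)}
        for d in self.detections:
            counts[d.pod_class] += 1
        return counts


def _parse_class(label: str, where: str) -> int:
    label = label.strip().lower()
    if label in CLASS_IDS:
        return CLASS_IDS[label]
    if label.isdigit() and int(label) in VALID_CLASSES:
        return int(label)
    raise DetectionError(f"{where}: unknown pod class label {label!r}")


def read_detections_csv(path: str | Path, plant_id: str | None = None,
                        view: str | None = None) -> PodSet:
    """Read the flat-CSV dialect into a PodSet.

    Rows are filtered to ``plant_id``/``view`` when given; otherwise all rows
    must agree on both.  An empty file yields an empty PodSet.
    """
    path = Path(path)
    dets: list[Detection] = []
    seen_plant, seen_view = plant_id, view
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return PodSet(plant_id=plant_id or "unknown", view=view or "front")
    header = [c.strip() for c in rows[0]]
    if header != CSV_HEADER:
        raise DetectionError(f"{path}: expected header {CSV_HEADER}, got {header}")
    for idx, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(CSV_HEADER):
            raise DetectionError(f"{path} row {idx}: expected {len(CSV_HEADER)} fields, got {len(row)}")
        pid, vw = row[0].strip(), row[1].strip()
        if plant_id is not None and pid != plant_id:
            continue
        if view is not None and vw != view:
            continue
        try:
            coords = [float(v) for v in row[2:6]]
            conf = float(row[7])
        except ValueError as exc:
            raise DetectionError(f"{path} row {idx}: {exc}") from exc
        if not all(math.isfinite(v) for v in coords):
            raise DetectionError(f"{path} row {idx}: non-finite coordinates")
        cls = _parse_class(row[6], f"{path} row {idx}")
        dets.append(Detection(BoundingBox(*coords), cls, conf, vw))
        seen_plant = seen_plant if seen_plant is not None else pid
        seen_view = seen_view if seen_view is not None else vw
        if pid != seen_plant or vw != seen_view:
            raise DetectionError(
                f"{path} row {idx}: mixed plant/view ({pid},{vw}) in single-set read; "
                "pass plant_id/view to filter")
    return PodSet(plant_id=seen_plant or "unknown", view=seen_view or "front", detections=dets)


def write_detections_csv(podsets: Iterable[PodSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for ps in podsets:
            for d in ps.detections:
                writer.writerow([
                    ps.plant_id, ps.view,
                    _fmt(d.box.x_min), _fmt(d.box.y_min), _fmt(d.box.x_max), _fmt(d.box.y_max),
                    CLASS_NAMES[d.pod_class], _fmt(d.confidence),
                ])


def _fmt(v: float) -> str:
    # integers print without a trailing .0 so CSV round-trips are byte-stable
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_detections_coco(path: str | Path, plant_id: str | None = None,
                         view: str | None = None) -> PodSet:
    """Read the COCO-style JSON dialect (subset: images/annotations/categories).

    Boxes are ``[x, y, w, h]`` and are converted to half-open corners.  The
    image record's ``file_name`` stem is parsed as ``<plant>_<view>``.
    """
    path = Path(path)
    with path.open() as fh:
        data = json.load(fh)
    cat_map: dict[int, int] = {}
    for cat in data.get("categories", []):
        cat_map[cat["id"]] = _parse_class(str(cat["name"]), f"{path} category {cat['id']}")
    images = {img["id"]: img for img in data.get("images", [])}
    dets: list[Detection] = []
    seen_plant, seen_view = plant_id, view
    for idx, ann in enumerate(data.get("annotations", [])):
        img = images.get(ann["image_id"])
        if img is None:
            raise DetectionError(f"{path} annotation {idx}: unknown image_id {ann['image_id']}")
        stem = Path(img["file_name"]).stem
        pid, _, vw = stem.rpartition("_")
        if vw not in VIEWS:
            raise DetectionError(f"{path} annotation {idx}: cannot parse view from {stem!r}")
        if plant_id is not None and pid != plant_id:
            continue
        if view is not None and vw != view:
            continue
        x, y, w, h = (float(v) for v in ann["bbox"])
        if not all(math.isfinite(v) for v in (x, y, w, h)):
            raise DetectionError(f"{path} annotation {idx}: non-finite coordinates")
        cls = cat_map.get(ann["category_id"])
        if cls is None:
            raise DetectionError(f"{path} annotation {idx}: unknown category_id {ann['category_id']}")
        conf = float(ann.get("score", 1.0))
        dets.append(Detection(BoundingBox.from_xywh(x, y, w, h), cls, conf, vw))
        seen_plant = seen_plant if seen_plant is not None else pid
        seen_view = seen_view if seen_view is not None else vw
    return PodSet(plant_id=seen_plant or "unknown", view=seen_view or "front", detections=dets)


def write_detections_coco(podsets: Iterable[PodSet], path: str | Path,
                          image_size: tuple[int, int] = (0, 0)) -> None:
    width, height = image_size
    images, annotations = [], []
    image_ids: dict[tuple[str, str], int] = {}
    for ps in podsets:
        key = (ps.plant_id, ps.view)
        if key not in image_ids:
            image_ids[key] = len(image_ids) + 1
            images.append({"id": image_ids[key], "file_name": f"{ps.plant_id}_{ps.view}.png",
                           "width": width, "height": height})
        for d in ps.detections:
            x, y, w, h = d.box.as_xywh()
            annotations.append({
                "id": len(annotations) + 1,
                "image_id": image_ids[key],
                "category_id": d.pod_class,
                "bbox": [x, y, w, h],
                "score": d.confidence,
            })
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": k, "name": v} for k, v in sorted(CLASS_NAMES.items())],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_detections(path: str | Path, dialect: str, plant_id: str | None = None,
                    view: str | None = None) -> PodSet:
    """Dispatch to the named dialect reader (``coco_json`` or ``flat_csv``)."""
    if dialect == "flat_csv":
        return read_detections_csv(path, plant_id=plant_id, view=view)
    if dialect == "coco_json":
        return read_detections_coco(path, plant_id=plant_id, view=view)
    raise ValueError(f"unknown detection dialect {dialect!r}")


def write_detections(podsets: Iterable[PodSet], path: str | Path, dialect: str,
                     image_size: tuple[int, int] = (0, 0)) -> None:
    if dialect == "flat_csv":
        write_detections_csv(podsets, path)
    elif dialect == "coco_json":
        write_detections_coco(podsets, path, image_size=image_size)
    else:
        raise ValueError(f"unknown detection dialect {dialect!r}")


def flip_boxes(podset: PodSet, image_width: float) -> PodSet:
    """Reflect boxes horizontally, realigning a mirrored rear view.

    ``x_min' = width - x_max``; y-coordinates, class, and confidence are kept.
    An involution: flipping twice at the same width restores the input.
    """
    flipped = []
    for d in podset.detections:
        b = d.box
        if b.x_min < 0 or b.x_max > image_width:
            raise DetectionError(f"box {b} outside image of width {image_width}")
        nb = BoundingBox(image_width - b.x_max, b.y_min, image_width - b.x_min, b.y_max)
        flipped.append(replace(d, box=nb))
    return PodSet(plant_id=podset.plant_id, view=podset.view, detections=flipped)
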