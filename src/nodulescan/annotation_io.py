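"""Readers and writers for the three concrete formats the pipeline touches.

* LabelMe JSON — rectangle annotations as two-corner point pairs;
* YOLO label text — one ``class cx cy w h`` line per object, normalized;
* detections CSV — final image-global boxes with confidences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import pandas as pd

from .geometry import (EPS, FRAME_IMAGE, Detection, GeometryError, PixelBox,
                       from_normalized, to_normalized)

log = logging.getLogger(__name__)

DETECTIONS_CSV_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


class AnnotationFormatError(ValueError):
    """Raised for structurally invalid annotation documents."""


@dataclass
class ImageAnnotationSet:
    """Ground-truth rectangles for one image.

    ``boxes`` are image-global (or patch-local, after remapping) pixel boxes,
    one per labeled nodule.
    """

    image_id: str
    image_w: float
    image_h: float
    boxes: list[PixelBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.image_id:
            raise AnnotationFormatError("image_id must be non-empty")
        if self.image_w <= 0 or self.image_h <= 0:
            raise AnnotationFormatError("image dimensions must be positive")


def _clamped_box(x0: float, y0: float, x1: float, y1: float,
                 image_w: float, image_h: float, image_id: str) -> PixelBox:
    # corners may come in any order; annotation boxes touching the border are
    # clamped to image bounds (with a warning) since the source format does not
    # guarantee clamping
    x_min, x_max = sorted((x0, x1))
    y_min, y_max = sorted((y0, y1))
    if (x_min < -EPS or y_min < -EPS
            or x_max > image_w + EPS or y_max > image_h + EPS):
        log.warning("clamping out-of-bounds box in %s: (%s, %s, %s, %s)",
                    image_id, x_min, y_min, x_max, y_max)
    return PixelBox(max(x_min, 0.0), max(y_min, 0.0),
                    min(x_max, image_w), min(y_max, image_h))


def read_labelme(document: str, image_id: str | None = None) -> ImageAnnotationSet:
    """Parse a LabelMe JSON document into an annotation set.

    Only ``rectangle`` shapes are kept; other shape types are skipped with a
    logged warning.  Image dimensions come from the ``imageWidth`` /
    ``imageHeight`` metadata fields (any embedded image payload is ignored).
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"not valid JSON: {exc}") from exc
    try:
        image_w = float(doc["imageWidth"])
        image_h = float(doc["imageHeight"])
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationFormatError("missing imageWidth/imageHeight") from exc
    if image_id is None:
        image_path = doc.get("imagePath") or ""
        image_id = image_path.rsplit("/", 1)[-1].rsplit(".", 1)[0] or "image"
    boxes: list[PixelBox] = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "rectangle":
            log.warning("skipping non-rectangle shape %r in %s",
                        shape.get("shape_type"), image_id)
            continue
        (x0, y0), (x1, y1) = shape["points"]
        boxes.append(_clamped_box(x0, y0, x1, y1, image_w, image_h, image_id))
    return ImageAnnotationSet(image_id, image_w, image_h, boxes)


def write_labelme(annotations: ImageAnnotationSet, image_path: str | None = None) -> str:
    """Serialize an annotation set as a LabelMe JSON document."""
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": "nodule",
                "points": [[b.x_min, b.y_min], [b.x_max, b.y_max]],
                "group_id": None,
                "shape_type": "rectangle",
                "flags": {},
            }
            for b in annotations.boxes
        ],
        "imagePath": image_path or f"{annotations.image_id}.png",
        "imageData": None,
        "imageHeight": annotations.image_h,
        "imageWidth": annotations.image_w,
    }
    return json.dumps(doc, indent=2)


def write_yolo_labels(annotations: ImageAnnotationSet) -> str:
    """One ``0 cx cy w h`` line per box, 6-decimal fixed formatting.

    The single object class (id 0) is the nodule.
    """
    lines = []
    for box in annotations.boxes:
        n = to_normalized(box, annotations.image_w, annotations.image_h)
        lines.append(f"{n.class_id} {n.cx:.6f} {n.cy:.6f} {n.w:.6f} {n.h:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_labels(text: str, image_w: float, image_h: float,
                     image_id: str = "image") -> ImageAnnotationSet:
    """Inverse of :func:`write_yolo_labels` via denormalization."""
    boxes: list[PixelBox] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise AnnotationFormatError(
                f"line {lineno}: expected 5 fields, got {len(fields)}")
        try:
            class_id = int(float(fields[0]))
            cx, cy, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise AnnotationFormatError(f"line {lineno}: non-numeric field") from exc
        from .geometry import NormalizedBox
        boxes.append(from_normalized(NormalizedBox(class_id, cx, cy, w, h),
                                     image_w, image_h))
    return ImageAnnotationSet(image_id, image_w, image_h, boxes)


def write_detections_csv(detections: Sequence[Detection], image_id: str) -> str:
    """Final-detections CSV for one image, with a stable deterministic order.

    Rows are sorted by ``y_min``, then ``x_min``, then confidence descending so
    repeated runs produce byte-identical files.
    """
    for det in detections:
        if det.frame != FRAME_IMAGE:
            raise GeometryError(
                f"detection in frame {det.frame!r}; stitch to image-global first")
    rows = sorted(
        ((image_id, float(d.box.x_min), float(d.box.y_min), float(d.box.x_max),
          float(d.box.y_max), float(d.confidence)) for d in detections),
        key=lambda r: (r[2], r[1], -r[5]),
    )
    df = pd.DataFrame(rows, columns=DETECTIONS_CSV_COLUMNS)
    return df.to_csv(index=False)


def read_detections_csv(text: str) -> dict[str, list[Detection]]:
    """Read a detections CSV back into per-image detection lists."""
    # round_trip parsing so written coordinates are recovered bit-exactly
    df = pd.read_csv(StringIO(text), float_precision="round_trip")
    missing = set(DETECTIONS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"detections CSV missing columns: {sorted(missing)}")
    out: dict[str, list[Detection]] = {}
    for row in df.itertuples(index=False):
        det = Detection(PixelBox(row.x_min, row.y_min, row.x_max, row.y_max),
                        float(row.confidence), frame=FRAME_IMAGE)
        out.setdefault(str(row.image_id), []).append(det)
    return out


def concat_detection_csvs(csvs: Iterable[str]) -> str:
    """Merge per-image detections CSVs into one multi-image table."""
    frames = [pd.read_csv(StringIO(c)) for c in csvs]
    if not frames:
        return pd.DataFrame(columns=DETECTIONS_CSV_COLUMNS).to_csv(index=False)
    return pd.concat(frames, ignore_index=True).to_csv(index=False)
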