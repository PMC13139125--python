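"""Core box geometry shared by every pipeline stage.

All coordinates are continuous, 0-based pixels with the origin at the image
top-left corner, x increasing rightward and y increasing downward.  Boxes are
closed real intervals stored as corner pairs; doing the geometry in continuous
coordinates avoids the off-by-one ambiguities of half-open pixel-grid
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

EPS = 1e-6

#: Frame tags for detections: patch-local before stitching, image-global after.
FRAME_PATCH = "patch-local"
FRAME_IMAGE = "image-global"


class GeometryError(ValueError):
    """Invalid box geometry (zero/negative extent, out-of-bounds, bad frame)."""


@dataclass(frozen=True, slots=True)
class PixelBox:
    """Axis-aligned rectangle with strictly positive extent.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Corner coordinates in pixels; ``x_max > x_min`` and ``y_max > y_min``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise GeometryError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def translate(self, dx: float, dy: float) -> "PixelBox":
        return PixelBox(self.x_min + dx, self.y_min + dy,
                        self.x_max + dx, self.y_max + dy)

    def clip(self, x_lo: float, y_lo: float, x_hi: float, y_hi: float) -> Optional["PixelBox"]:
        """Intersect with a clipping window; ``None`` when the overlap is empty."""
        x0 = max(self.x_min, x_lo)
        y0 = max(self.y_min, y_lo)
        x1 = min(self.x_max, x_hi)
        y1 = min(self.y_max, y_hi)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            return None
        return PixelBox(x0, y0, x1, y1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True, slots=True)
class Detection:
    """A detector output: a box, a confidence score, and a coordinate frame."""

    box: PixelBox
    confidence: float
    frame: str = FRAME_IMAGE
    patch_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise GeometryError(f"confidence {self.confidence} outside [0, 1]")
        if self.frame not in (FRAME_PATCH, FRAME_IMAGE):
            raise GeometryError(f"unknown frame {self.frame!r}")

    def translate(self, dx: float, dy: float, frame: Optional[str] = None) -> "Detection":
        return replace(self, box=self.box.translate(dx, dy),
                       frame=self.frame if frame is None else frame)


@dataclass(frozen=True, slots=True)
class NormalizedBox:
    """A box in YOLO-style normalized center/size coordinates."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise GeometryError(f"normalized size ({self.w}, {self.h}) outside (0, 1]")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise GeometryError(f"normalized center ({self.cx}, {self.cy}) outside [0, 1]")
        if (self.cx - self.w / 2 < -EPS or self.cx + self.w / 2 > 1 + EPS
                or self.cy - self.h / 2 < -EPS or self.cy + self.h / 2 > 1 + EPS):
            raise GeometryError("normalized box extends beyond the unit square")


def iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def to_normalized(box: PixelBox, image_w: float, image_h: float,
                  class_id: int = 0) -> NormalizedBox:
    """Convert a pixel box to normalized center/size coordinates.

    Normalization is relative to the source image dimensions; the box must lie
    within the image up to a small tolerance.
    """
    if image_w <= 0 or image_h <= 0:
        raise GeometryError("image dimensions must be positive")
    tol_x = EPS * max(1.0, image_w)
    tol_y = EPS * max(1.0, image_h)
    if (box.x_min < -tol_x or box.y_min < -tol_y
            or box.x_max > image_w + tol_x or box.y_max > image_h + tol_y):
        raise GeometryError(
            f"box {box.as_tuple()} exceeds image bounds {image_w}x{image_h}")
    cx, cy = box.center
    return NormalizedBox(class_id, cx / image_w, cy / image_h,
                         box.width / image_w, box.height / image_h)


def from_normalized(n: NormalizedBox, image_w: float, image_h: float) -> PixelBox:
    """Exact algebraic inverse of :func:`to_normalized`."""
    if image_w <= 0 or image_h <= 0:
        raise GeometryError("image dimensions must be positive")
    cx = n.cx * image_w
    cy = n.cy * image_h
    w = n.w * image_w
    h = n.h * image_h
    return PixelBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
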