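"""Stitch-back and detection refinement.

After per-patch inference, detections are (1) filtered against patch edges —
a box hugging a patch boundary is an unreliable partial view whose nodule is
fully captured in a neighboring patch — (2) translated back into full-image
coordinates, and (3) deduplicated with greedy non-maximum suppression, since
a nodule inside the overlap band is detected once per adjacent patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .geometry import FRAME_IMAGE, FRAME_PATCH, Detection, GeometryError, iou
from .tiler import PatchSpec


@dataclass(frozen=True)
class PostprocessConfig:
    """Edge-filter and NMS parameters.

    ``edge_threshold`` is the minimum allowed distance (px) between any box
    side and a patch boundary.  ``exempt_image_border`` keeps detections that
    hug a patch boundary coinciding with the photo's outer border: such a
    nodule exists only in that border patch and would otherwise be lost.
    """

    edge_threshold: float = 5.0
    nms_confidence: float = 0.2
    nms_iou: float = 0.2
    exempt_image_border: bool = True

    def __post_init__(self) -> None:
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be non-negative")
        if not (0.0 <= self.nms_confidence <= 1.0 and 0.0 <= self.nms_iou <= 1.0):
            raise ValueError("NMS thresholds must be in [0, 1]")


def edge_filter(detections: Sequence[Detection], spec: PatchSpec,
                image_w: float, image_h: float,
                config: PostprocessConfig = PostprocessConfig()) -> list[Detection]:
    """Drop detections whose box lies within ``edge_threshold`` px of a patch edge.

    Operates in the patch-local frame, where "patch edge" is well defined.
    A boundary that coincides with the image border is exempt when
    ``exempt_image_border`` is set.
    """
    t = config.edge_threshold
    exempt = config.exempt_image_border
    left_is_border = exempt and spec.x0 <= 0
    top_is_border = exempt and spec.y0 <= 0
    right_is_border = exempt and spec.x0 + spec.width >= image_w
    bottom_is_border = exempt and spec.y0 + spec.height >= image_h
    kept: list[Detection] = []
    for det in detections:
        if det.frame != FRAME_PATCH:
            raise GeometryError("edge_filter expects patch-local detections")
        b = det.box
        near = ((not left_is_border and b.x_min < t)
                or (not top_is_border and b.y_min < t)
                or (not right_is_border and spec.width - b.x_max < t)
                or (not bottom_is_border and spec.height - b.y_max < t))
        if not near:
            kept.append(det)
    return kept


def translate_to_global(detections: Sequence[Detection],
                        spec: PatchSpec) -> list[Detection]:
    """Shift patch-local detections by the patch origin into the image frame."""
    out: list[Detection] = []
    for det in detections:
        if det.frame != FRAME_PATCH:
            raise GeometryError("detection already in image-global frame")
        out.append(det.translate(spec.x0, spec.y0, frame=FRAME_IMAGE))
    return out


def nms(detections: Sequence[Detection],
        config: PostprocessConfig = PostprocessConfig()) -> list[Detection]:
    """Confidence floor, then greedy IoU suppression.

    Detections below ``nms_confidence`` are dropped first.  The remainder are
    sorted by confidence descending (ties broken by x_min then y_min
    ascending); the top box is kept and every remaining box with IoU >=
    ``nms_iou`` against it is removed.  Output order is acceptance order.
    """
    pool = [d for d in detections if d.confidence >= config.nms_confidence]
    pool.sort(key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    while pool:
        top = pool.pop(0)
        kept.append(top)
        pool = [d for d in pool if iou(top.box, d.box) < config.nms_iou]
    return kept


def refine_image(per_patch: Iterable[tuple[PatchSpec, Sequence[Detection]]],
                 plan: Sequence[PatchSpec], image_w: float, image_h: float,
                 config: PostprocessConfig = PostprocessConfig()) -> list[Detection]:
    """Full refinement chain: per-patch edge filter -> stitch -> pooled NMS."""
    known = {s.name for s in plan}
    pooled: list[Detection] = []
    for spec, dets in per_patch:
        if spec.name not in known:
            raise ValueError(f"patch {spec.name} is not in the patch plan")
        pooled.extend(translate_to_global(
            edge_filter(dets, spec, image_w, image_h, config), spec))
    return nms(pooled, config)
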