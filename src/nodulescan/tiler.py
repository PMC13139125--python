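"""Overlap tiling of large root images into fixed-size detector patches.

A full-resolution root photograph (roughly 2,300 x 4,600 px) is decomposed
into 512 x 512 patches with a 64-px overlap between neighbors, so that any
nodule no larger than the overlap is fully contained in at least one patch.
Annotations are remapped into patch-local coordinates alongside the pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import ImageAnnotationSet
from .geometry import PixelBox

MANIFEST_COLUMNS = ["image_id", "row", "col", "x0", "y0",
                    "patch_size", "image_w", "image_h"]


@dataclass(frozen=True)
class TilerConfig:
    """Patch size and inter-patch overlap, both in pixels."""

    patch_size: int = 512
    overlap: int = 64

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.patch_size):
            raise ValueError("require 0 <= overlap < patch_size")

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap


@dataclass(frozen=True)
class PatchSpec:
    """Placement of one tile inside its source image.

    ``(x0, y0)`` is the patch origin in image-global pixels; the patch covers
    ``[x0, x0 + width) x [y0, y0 + height)``.
    """

    image_id: str
    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int

    @property
    def name(self) -> str:
        return f"{self.image_id}_r{self.row}_c{self.col}"


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    # grid at 0, stride, 2*stride, ... with the last origin clamped so the
    # final patch ends exactly at the image border; a single zero-padded patch
    # when the image is smaller than the patch
    if dim <= patch:
        return [0]
    n = math.ceil((dim - patch) / stride) + 1
    origins = [min(i * stride, dim - patch) for i in range(n)]
    # clamping can duplicate the final origin when stride divides dim - patch
    dedup: list[int] = []
    for o in origins:
        if not dedup or o > dedup[-1]:
            dedup.append(o)
    return dedup


def plan_patches(image_w: int, image_h: int, config: TilerConfig = TilerConfig(),
                 image_id: str = "image") -> list[PatchSpec]:
    """Deterministic patch grid covering every pixel of the image."""
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image dimensions must be positive")
    xs = _axis_origins(image_w, config.patch_size, config.stride)
    ys = _axis_origins(image_h, config.patch_size, config.stride)
    return [
        PatchSpec(image_id, row, col, x0, y0, config.patch_size, config.patch_size)
        for row, y0 in enumerate(ys)
        for col, x0 in enumerate(xs)
    ]


def crop_patch(image: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Pixel-exact crop; regions beyond the image are zero-filled.

    Zero padding can only occur when the image is smaller than the patch,
    since interior origins are clamped to keep patches inside the image.
    """
    h, w = image.shape[:2]
    if spec.x0 < 0 or spec.y0 < 0 or (spec.x0 > 0 and spec.x0 + spec.width > w) \
            or (spec.y0 > 0 and spec.y0 + spec.height > h):
        raise ValueError(f"patch {spec.name} does not belong to a {w}x{h} image")
    out_shape = (spec.height, spec.width) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    src = image[spec.y0:spec.y0 + spec.height, spec.x0:spec.x0 + spec.width]
    out[:src.shape[0], :src.shape[1]] = src
    return out


def remap_labels(annotations: ImageAnnotationSet, spec: PatchSpec) -> ImageAnnotationSet:
    """Translate boxes into patch-local coordinates, clipped to the patch.

    Boxes with no overlap with the patch are excluded, so the result holds
    only the nodules (possibly partially) visible within the patch.
    """
    if annotations.image_id != spec.image_id:
        raise ValueError(
            f"annotation set {annotations.image_id!r} does not match patch "
            f"image {spec.image_id!r}")
    local: list[PixelBox] = []
    for box in annotations.boxes:
        clipped = box.translate(-spec.x0, -spec.y0).clip(
            0.0, 0.0, float(spec.width), float(spec.height))
        if clipped is not None:
            local.append(clipped)
    return ImageAnnotationSet(spec.name, spec.width, spec.height, local)


def write_manifest(plan: Sequence[PatchSpec], image_w: int, image_h: int) -> str:
    """Self-describing patch manifest CSV so stitching needs no extra state."""
    rows = [(s.image_id, s.row, s.col, s.x0, s.y0, s.width, image_w, image_h)
            for s in plan]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(index=False)


def read_manifest(text: str) -> tuple[dict[str, list[PatchSpec]], dict[str, tuple[int, int]]]:
    """Read a manifest back into per-image patch plans and image dimensions."""
    df = pd.read_csv(StringIO(text))
    plans: dict[str, list[PatchSpec]] = {}
    dims: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        spec = PatchSpec(str(row.image_id), int(row.row), int(row.col),
                         int(row.x0), int(row.y0),
                         int(row.patch_size), int(row.patch_size))
        plans.setdefault(spec.image_id, []).append(spec)
        dims[spec.image_id] = (int(row.image_w), int(row.image_h))
    return plans, dims
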