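"""Synthetic root scenes with ground truth, and a controllable mock detector.

The generator emulates the imaging setup the pipeline targets: a root washed
onto blue blotter paper, photographed top-down, with nodules appearing as
small tan elliptical protrusions scattered near a sinuous vertical taproot.
Nodule sizes follow a truncated lognormal whose mean and hard maximum default
to the measured statistics of real test images (mean side 19.93 px, maximum
57 px).  Every scene carries exact bounding-box ground truth, so each
pipeline stage can be tested without any trained model or image download.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import ImageAnnotationSet
from .geometry import FRAME_IMAGE, Detection, PixelBox, iou

BACKGROUND_RGB = (86, 118, 170)   # blue blotter paper
ROOT_RGB = (60, 66, 92)           # wet root stripe, darker and desaturated
NODULE_RGB = (181, 141, 96)       # tan nodule fill


class PackingError(RuntimeError):
    """Could not place the requested nodules at the required separation."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic root scene.

    ``size_mean`` / ``size_max`` control the larger box side ("nodule
    length"); ``min_separation`` is the guaranteed pixel gap between boxes,
    which makes all ground-truth pairs strictly disjoint (pairwise IoU 0).
    """

    image_w: int = 2300
    image_h: int = 4600
    n_nodules: int = 25
    size_mean: float = 19.93
    size_max: float = 57.0
    size_min: float = 6.0
    size_sigma: float = 0.45
    min_separation: float = 10.0
    along_root_layout: bool = True
    qr_decoy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.size_max >= self.size_mean > 0):
            raise ValueError("require size_max >= size_mean > 0")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be non-negative")


@dataclass(frozen=True)
class MockDetectorConfig:
    """Error model for the mock detector.

    Each ground-truth box is independently missed with probability
    ``fn_rate``; surviving boxes get Gaussian corner jitter of ``jitter_sd``
    pixels and a confidence drawn uniformly from ``confidence_range``.
    Spurious boxes are added with a Poisson count of mean ``fp_per_image``,
    placed disjoint from all ground truth.
    """

    jitter_sd: float = 0.0
    fn_rate: float = 0.0
    fp_per_image: float = 0.0
    confidence_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn_rate <= 1.0):
            raise ValueError("fn_rate must be in [0, 1]")
        lo, hi = self.confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("confidence_range must be within [0, 1]")


def _separated(a: tuple[float, float, float, float],
               b: tuple[float, float, float, float], gap: float) -> bool:
    return (a[2] + gap <= b[0] or b[2] + gap <= a[0]
            or a[3] + gap <= b[1] or b[3] + gap <= a[1])


def _root_center_x(ys: np.ndarray, image_w: int, image_h: int,
                   rng: np.random.Generator,
                   phase: float, amplitude: float) -> np.ndarray:
    # sinuous vertical taproot: slow sine wiggle around the image midline
    return image_w / 2.0 + amplitude * np.sin(
        2.0 * np.pi * ys / max(image_h, 1) * 1.5 + phase)


def sample_ground_truth(config: SceneConfig) -> tuple[ImageAnnotationSet, dict]:
    """Sample nodule boxes (no rendering) plus the layout needed to draw them.

    Returns the annotation set and a dict of per-nodule geometry (centers,
    radii) and root-curve parameters consumed by :func:`generate_scene`.
    """
    rng = np.random.default_rng(config.seed)
    phase = rng.uniform(0, 2 * np.pi)
    amplitude = rng.uniform(0.05, 0.15) * config.image_w
    layout = {"phase": phase, "amplitude": amplitude,
              "root_halfwidth": rng.uniform(14, 26),
              "centers": [], "radii": []}

    mu = np.log(config.size_mean) - config.size_sigma ** 2 / 2.0
    margin = 2.0
    placed: list[tuple[float, float, float, float]] = []
    boxes: list[PixelBox] = []
    budget = 400 * max(config.n_nodules, 1)
    attempts = 0
    while len(boxes) < config.n_nodules:
        attempts += 1
        if attempts > budget:
            raise PackingError(
                f"placed only {len(boxes)}/{config.n_nodules} nodules within "
                f"the retry budget")
        # larger box side from a truncated lognormal; minor side is a fraction
        major = float(rng.lognormal(mu, config.size_sigma))
        if not (config.size_min <= major <= config.size_max):
            continue
        minor = major * rng.uniform(0.65, 1.0)
        w, h = (major, minor) if rng.random() < 0.5 else (minor, major)
        cy = rng.uniform(margin + h / 2, config.image_h - margin - h / 2)
        if config.along_root_layout:
            rx = _root_center_x(np.asarray([cy]), config.image_w, config.image_h,
                                rng, phase, amplitude)[0]
            cx = rx + rng.normal(0.0, 0.12 * config.image_w)
        else:
            cx = rng.uniform(margin + w / 2, config.image_w - margin - w / 2)
        if not (margin + w / 2 <= cx <= config.image_w - margin - w / 2):
            continue
        cand = (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        if all(_separated(cand, p, config.min_separation) for p in placed):
            placed.append(cand)
            boxes.append(PixelBox(*cand))
            layout["centers"].append((cx, cy))
            layout["radii"].append((w / 2, h / 2))
    annotations = ImageAnnotationSet(f"scene{config.seed}",
                                     config.image_w, config.image_h, boxes)
    return annotations, layout


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, ImageAnnotationSet]:
    """Render one synthetic root scene with tight ground-truth boxes.

    Deterministic given ``config.seed``: repeated calls return a byte-identical
    image and identical boxes.
    """
    from skimage.draw import ellipse

    annotations, layout = sample_ground_truth(config)
    img = np.empty((config.image_h, config.image_w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB

    ys = np.arange(config.image_h)
    root_cx = _root_center_x(ys, config.image_w, config.image_h,
                             np.random.default_rng(config.seed),
                             layout["phase"], layout["amplitude"])
    xs = np.arange(config.image_w)
    root_mask = np.abs(xs[None, :] - root_cx[:, None]) < layout["root_halfwidth"]
    img[root_mask] = ROOT_RGB

    if config.qr_decoy:
        _stamp_qr_decoy(img, np.random.default_rng(config.seed + 1))

    shade = np.random.default_rng(config.seed + 2)
    for (cx, cy), (rx, ry) in zip(layout["centers"], layout["radii"]):
        rr, cc = ellipse(cy, cx, ry, rx, shape=img.shape[:2])
        jitter = shade.integers(-12, 13, size=3)
        img[rr, cc] = np.clip(np.asarray(NODULE_RGB) + jitter, 0, 255).astype(np.uint8)
    return img, annotations


def _stamp_qr_decoy(img: np.ndarray, rng: np.random.Generator) -> None:
    # dark QR-like dot grid in the top-left corner: a negative control for
    # intensity-based detectors (label tags must not be read as nodules)
    size, cell = 120, 6
    block = rng.random((size // cell, size // cell)) < 0.5
    patch = np.kron(block, np.ones((cell, cell), dtype=bool))
    region = img[20:20 + size, 20:20 + size]
    region[patch] = (25, 25, 30)
    region[~patch] = (235, 235, 235)


def corrupt_boxes(boxes: Sequence[PixelBox], config: MockDetectorConfig,
                  rng: np.random.Generator, bounds: tuple[float, float],
                  frame: str = FRAME_IMAGE, patch_id: str | None = None
                  ) -> list[Detection]:
    """Apply the mock error model to a box list (shared by both mock paths)."""
    w_bound, h_bound = bounds
    lo, hi = config.confidence_range
    out: list[Detection] = []
    for box in boxes:
        if rng.random() < config.fn_rate:
            continue
        if config.jitter_sd > 0:
            d = rng.normal(0.0, config.jitter_sd, size=4)
            jittered = PixelBox(
                min(box.x_min + d[0], box.x_max + d[2] - 1e-3),
                min(box.y_min + d[1], box.y_max + d[3] - 1e-3),
                max(box.x_max + d[2], box.x_min + d[0] + 1e-3),
                max(box.y_max + d[3], box.y_min + d[1] + 1e-3),
            )
        else:
            jittered = box
        conf = float(rng.uniform(lo, hi)) if hi > lo else float(hi)
        out.append(Detection(jittered, conf, frame=frame, patch_id=patch_id))
    n_fp = int(rng.poisson(config.fp_per_image)) if config.fp_per_image > 0 else 0
    for _ in range(n_fp):
        for _attempt in range(200):
            side = float(rng.uniform(8, 30))
            x0 = float(rng.uniform(0, max(w_bound - side, 1)))
            y0 = float(rng.uniform(0, max(h_bound - side, 1)))
            fp = PixelBox(x0, y0, x0 + side, y0 + side)
            if all(iou(fp, b) == 0.0 for b in boxes):
                conf = float(rng.uniform(lo, hi)) if hi > lo else float(hi)
                out.append(Detection(fp, conf, frame=frame, patch_id=patch_id))
                break
    return out


def mock_detect(gt: ImageAnnotationSet, config: MockDetectorConfig) -> list[Detection]:
    """Corrupt image-global ground truth into a mock detection list.

    Deterministic given ``config.seed`` and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    return corrupt_boxes(gt.boxes, config, rng, (gt.image_w, gt.image_h))


def stable_patch_seed(base_seed: int, patch_name: str) -> int:
    """Per-patch RNG seed independent of patch processing order."""
    return (base_seed * 1_000_003 + zlib.crc32(patch_name.encode())) % (2 ** 31)


def make_paper_confusion_fixture() -> tuple[list[PixelBox], list[Detection]]:
    """Constructed scene with a known confusion matrix at any IoU threshold.

    559 pairwise-disjoint ground-truth boxes; predictions are verbatim copies
    of the first 515 of them (IoU 1 with their source, 0 with all others)
    plus 62 spurious boxes disjoint from every ground-truth box.  Matching
    therefore yields TP=515, FN=44, FP=62 at any threshold in (0, 1].
    """
    gt: list[PixelBox] = []
    cols = 24
    for i in range(559):
        r, c = divmod(i, cols)
        x0, y0 = 10 + 40 * c, 10 + 40 * r
        gt.append(PixelBox(x0, y0, x0 + 20, y0 + 20))
    preds = [Detection(b, 0.9, frame=FRAME_IMAGE) for b in gt[:515]]
    # spurious boxes in the 30..40 px gap rows between ground-truth rows
    fp_y0 = 10 + 40 * ((559 // cols) + 2)
    for j in range(62):
        r, c = divmod(j, cols)
        x0, y0 = 10 + 40 * c, fp_y0 + 40 * r
        preds.append(Detection(PixelBox(x0, y0, x0 + 20, y0 + 20), 0.8,
                               frame=FRAME_IMAGE))
    return gt, preds
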