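"""Pluggable per-patch detector backends.

The pipeline is detector-agnostic: any backend that maps a patch raster to a
list of patch-local detections can drive it.  Three backends are provided:

* ``mock`` — replays attached ground truth through a configurable error model
  (jitter, misses, spurious boxes); the test oracle.
* ``blob`` — classical color-threshold + connected-component detector, so the
  pipeline can run on actual pixels without a trained model.
* ``yolo`` — thin adapter around externally trained YOLO weights (optional;
  requires the ``ultralytics`` package and a weights file).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .annotation_io import ImageAnnotationSet
from .geometry import FRAME_PATCH, Detection, PixelBox
from .synthetic import MockDetectorConfig, corrupt_boxes, stable_patch_seed
from .tiler import PatchSpec

BACKENDS = ("mock", "blob", "yolo")


class DetectorConfigError(ValueError):
    """Unknown backend or unusable backend parameters."""


@dataclass(frozen=True)
class DetectorSpec:
    """Backend selection plus backend-specific parameters and a seed."""

    backend: str = "mock"
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise DetectorConfigError(
                f"unknown backend {self.backend!r}; expected one of {BACKENDS}")


class Detector(Protocol):
    def detect(self, patch: np.ndarray, spec: PatchSpec) -> list[Detection]: ...


class MockPatchDetector:
    """Oracle backend: corrupts patch-local ground truth deterministically.

    The per-patch RNG is derived from the base seed and the patch name, so
    results do not depend on patch processing order.
    """

    def __init__(self, ground_truth: Mapping[str, ImageAnnotationSet],
                 config: MockDetectorConfig):
        self.ground_truth = dict(ground_truth)
        self.config = config

    def detect(self, patch: np.ndarray, spec: PatchSpec) -> list[Detection]:
        local = self.ground_truth.get(spec.name)
        boxes: Sequence[PixelBox] = local.boxes if local is not None else []
        rng = np.random.default_rng(stable_patch_seed(self.config.seed, spec.name))
        return corrupt_boxes(boxes, self.config, rng,
                             (float(spec.width), float(spec.height)),
                             frame=FRAME_PATCH, patch_id=spec.name)


class BlobDetector:
    """Classical detector: nodules are warm (red > blue) blobs on blue paper.

    Thresholds the red-minus-blue channel difference, labels connected
    components, and keeps components within a plausible nodule area range.
    Confidence is the component's fill fraction of its bounding box (an
    ellipse fills ~pi/4 of its box).
    """

    def __init__(self, channel_diff: float = 30.0, min_area: float = 12.0,
                 max_area: float = 6000.0):
        self.channel_diff = channel_diff
        self.min_area = min_area
        self.max_area = max_area

    def detect(self, patch: np.ndarray, spec: PatchSpec) -> list[Detection]:
        from skimage.measure import label, regionprops

        if patch.ndim != 3 or patch.shape[2] < 3:
            raise DetectorConfigError("blob backend requires an RGB patch")
        diff = patch[..., 0].astype(np.int16) - patch[..., 2].astype(np.int16)
        mask = diff > self.channel_diff
        out: list[Detection] = []
        for region in regionprops(label(mask)):
            if not (self.min_area <= region.area <= self.max_area):
                continue
            minr, minc, maxr, maxc = region.bbox
            fill = float(region.area) / ((maxr - minr) * (maxc - minc))
            out.append(Detection(PixelBox(minc, minr, maxc, maxr),
                                 min(1.0, fill), frame=FRAME_PATCH,
                                 patch_id=spec.name))
        return out


class YoloAdapter:
    """Adapter around externally trained YOLO weights (never a silent fallback)."""

    def __init__(self, weights: str | None = None, conf: float = 0.001,
                 **predict_kwargs):
        import os
        if not weights or not os.path.exists(weights):
            raise DetectorConfigError(
                f"yolo backend requires an existing weights file, got {weights!r}")
        try:
            from ultralytics import YOLO  # type: ignore[import-not-found]
        except ImportError as exc:
            raise DetectorConfigError(
                "yolo backend requires the optional 'ultralytics' package") from exc
        self.model = YOLO(weights)
        self.conf = conf
        self.predict_kwargs = predict_kwargs

    def detect(self, patch: np.ndarray, spec: PatchSpec) -> list[Detection]:
        result = self.model.predict(patch, conf=self.conf, verbose=False,
                                    **self.predict_kwargs)[0]
        out: list[Detection] = []
        for xyxy, conf in zip(result.boxes.xyxy.tolist(),
                              result.boxes.conf.tolist()):
            out.append(Detection(PixelBox(*xyxy), float(conf),
                                 frame=FRAME_PATCH, patch_id=spec.name))
        return out


def build_detector(spec: DetectorSpec,
                   ground_truth: Mapping[str, ImageAnnotationSet] | None = None
                   ) -> Detector:
    """Instantiate the backend named by ``spec``.

    The mock backend needs patch-local ground truth (keyed by patch name),
    either passed here or under ``spec.params['ground_truth']``.
    """
    params = dict(spec.params)
    if spec.backend == "mock":
        gt = ground_truth if ground_truth is not None else params.pop("ground_truth", None)
        if gt is None:
            raise DetectorConfigError("mock backend requires attached ground truth")
        config = params.pop("config", None) or MockDetectorConfig(
            seed=spec.seed, **params)
        return MockPatchDetector(gt, config)
    if spec.backend == "blob":
        return BlobDetector(**params)
    return YoloAdapter(**params)
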