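"""The 24 nodulation traits computed from one image's final detections.

Six spatial-layout traits — nodule count, vertical/horizontal extent of the
nodulated zone (from box centers), dispersion of centers along each axis
(sdx, sdy) and their ratio (sdxy) — plus nine order/moment statistics of the
per-nodule bounding-box area (a 2D size proxy) and nine of the center
y-coordinate (a rooting-depth proxy): min, max, standard deviation, mean,
median, and the 5th/25th/75th/95th percentiles of each.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence, Union

import numpy as np

from .geometry import Detection, PixelBox

log = logging.getLogger(__name__)

_STAT_SUFFIXES = ["min", "max", "std", "mean", "median", "p5", "p25", "p75", "p95"]

#: The fixed 24-trait schema, in phenotype-CSV column order.
TRAIT_NAMES: tuple[str, ...] = tuple(
    ["count", "height", "width", "sdx", "sdy", "sdxy"]
    + [f"box_area_{s}" for s in _STAT_SUFFIXES]
    + [f"y_center_{s}" for s in _STAT_SUFFIXES]
)
assert len(TRAIT_NAMES) == 24

BoxLike = Union[Detection, PixelBox]


def _boxes(detections: Sequence[BoxLike]) -> list[PixelBox]:
    return [d.box if isinstance(d, Detection) else d for d in detections]


def _nine_stats(values: np.ndarray, ddof: int) -> dict[str, float]:
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "std": float(values.std(ddof=ddof)) if values.size > ddof else 0.0,
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "p5": float(np.percentile(values, 5)),
        "p25": float(np.percentile(values, 25)),
        "p75": float(np.percentile(values, 75)),
        "p95": float(np.percentile(values, 95)),
    }


def extract_traits(detections: Sequence[BoxLike], ddof: int = 0) -> dict[str, float]:
    """Compute the 24-trait vector for one image.

    Always returns exactly the :data:`TRAIT_NAMES` keys in schema order.
    Degenerate inputs never raise: with no nodules every trait but
    ``count`` is NaN; with one nodule all dispersions are 0 and ``sdxy``
    (0/0) is NaN.  Standard deviations are population SDs by default
    (``ddof=0``); percentiles interpolate linearly between closest ranks.
    """
    boxes = _boxes(detections)
    traits: dict[str, float] = {name: math.nan for name in TRAIT_NAMES}
    traits["count"] = float(len(boxes))
    if not boxes:
        return traits

    centers = np.array([b.center for b in boxes])
    areas = np.array([b.area for b in boxes])
    cx, cy = centers[:, 0], centers[:, 1]

    traits["width"] = float(cx.max() - cx.min())
    traits["height"] = float(cy.max() - cy.min())
    sdx = float(cx.std(ddof=ddof)) if cx.size > ddof else 0.0
    sdy = float(cy.std(ddof=ddof)) if cy.size > ddof else 0.0
    traits["sdx"] = sdx
    traits["sdy"] = sdy
    if sdy > 0:
        traits["sdxy"] = sdx / sdy
    elif sdx > 0:
        log.warning("sdy is 0 with sdx > 0: sdxy undefined for this image")

    for prefix, values in (("box_area", areas), ("y_center", cy)):
        for suffix, value in _nine_stats(values, ddof).items():
            traits[f"{prefix}_{suffix}"] = value
    return traits
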