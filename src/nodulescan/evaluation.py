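"""Detection-quality protocol: IoU matching, per-image metrics, count-binned reports.

Predictions are matched one-to-one to manually annotated ground truth by
greedy descending IoU at a configurable threshold; the resulting per-image
confusion counts yield precision, recall, and F1.  Images are then stratified
into nodule-count bins, per-image metrics are averaged within each bin, and
the headline number is the unweighted mean of the per-bin means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .geometry import Detection, PixelBox, iou

BoxLike = Union[Detection, PixelBox]

#: Default bin cut points giving bins <=5, 6-10, 11-20, 21-30, >=31 nodules.
DEFAULT_BIN_EDGES: tuple[int, ...] = (5, 10, 20, 30)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-image TP/FP/FN; the atom from which all metrics derive."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalConfig:
    """Matching IoU threshold and nodule-count bin edges."""

    match_iou: float = 0.5
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if not (0.0 < self.match_iou <= 1.0):
            raise ValueError("match_iou must be in (0, 1]")
        if list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise ValueError("bin_edges must be strictly increasing")


@dataclass(frozen=True)
class BinReport:
    """Unweighted per-bin means of the per-image metrics."""

    bin_label: str
    n_images: int
    mean_precision: float
    mean_recall: float
    mean_f1: float


def _box(d: BoxLike) -> PixelBox:
    return d.box if isinstance(d, Detection) else d


def match_detections(predictions: Sequence[BoxLike],
                     ground_truth: Sequence[BoxLike],
                     config: EvalConfig = EvalConfig()) -> ConfusionCounts:
    """Greedy one-to-one matching on descending pairwise IoU.

    A prediction/ground-truth pair is a match candidate iff their IoU is at
    least ``config.match_iou``; candidates are consumed best-first, each box
    used at most once.  Ties are broken by prediction index then ground-truth
    index, making the result permutation-reproducible.
    """
    pred_boxes = [_box(p) for p in predictions]
    gt_boxes = [_box(g) for g in ground_truth]
    candidates = []
    for i, p in enumerate(pred_boxes):
        for j, g in enumerate(gt_boxes):
            score = iou(p, g)
            if score >= config.match_iou:
                candidates.append((-score, i, j))
    candidates.sort()
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    tp = 0
    for _, i, j in candidates:
        if i in used_pred or j in used_gt:
            continue
        used_pred.add(i)
        used_gt.add(j)
        tp += 1
    counts = ConfusionCounts(tp, len(pred_boxes) - tp, len(gt_boxes) - tp)
    assert counts.tp + counts.fn == len(gt_boxes)
    assert counts.tp + counts.fp == len(pred_boxes)
    return counts


def image_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 from one image's confusion counts.

    Zero-denominator conventions: an image with no ground truth and no
    predictions scores (1, 1, 1) — vacuously perfect agreement; an undefined
    precision or recall with the other side non-empty resolves to 0.
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return (1.0, 1.0, 1.0)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return (precision, recall, f1)


def bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"<={edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">={edges[-1] + 1}")
    return labels


def assign_bin(gt_count: int, edges: Sequence[int] = DEFAULT_BIN_EDGES) -> str:
    """Bin label for an image's manually labeled nodule count."""
    labels = bin_labels(edges)
    for k, edge in enumerate(edges):
        if gt_count <= edge:
            return labels[k]
    return labels[-1]


def bin_report(per_image: Sequence[tuple[int, float, float, float]],
               config: EvalConfig = EvalConfig()) -> list[BinReport]:
    """Per-bin unweighted means plus an overall row averaging the bin means.

    ``per_image`` rows are ``(gt_count, precision, recall, f1)``.  Empty bins
    are omitted from both the report and the overall average.  The overall
    row weights each occupied bin equally, not each image.
    """
    buckets: dict[str, list[tuple[float, float, float]]] = {}
    for gt_count, p, r, f in per_image:
        buckets.setdefault(assign_bin(gt_count, config.bin_edges), []).append((p, r, f))
    report: list[BinReport] = []
    for label in bin_labels(config.bin_edges):
        rows = buckets.get(label)
        if not rows:
            continue
        n = len(rows)
        report.append(BinReport(
            label, n,
            sum(r[0] for r in rows) / n,
            sum(r[1] for r in rows) / n,
            sum(r[2] for r in rows) / n,
        ))
    if report:
        nb = len(report)
        report.append(BinReport(
            "overall", sum(b.n_images for b in report),
            sum(b.mean_precision for b in report) / nb,
            sum(b.mean_recall for b in report) / nb,
            sum(b.mean_f1 for b in report) / nb,
        ))
    return report


def report_to_csv(report: Sequence[BinReport]) -> str:
    """Serialize a bin report as the evaluation CSV."""
    df = pd.DataFrame(
        [(b.bin_label, b.n_images, b.mean_precision, b.mean_recall, b.mean_f1)
         for b in report],
        columns=["bin", "n_images", "precision", "recall", "f1"],
    )
    return df.to_csv(index=False)
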