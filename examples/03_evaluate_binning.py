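"""Score an imperfect detector and report count-binned precision/recall/F1.

Simulates 40 scenes with varying nodule loads, corrupts the ground truth
with a 10% miss rate and ~2 spurious boxes per image, matches predictions to
truth one-to-one at IoU 0.5, and prints the per-bin report.  Bins stratify
images by true nodule count (<=5 ... >=31); the overall row averages the
bins with equal weight.
"""

import numpy as np

from nodulescan import (MockDetectorConfig, SceneConfig, bin_report,
                        image_metrics, match_detections, mock_detect,
                        sample_ground_truth)

rng = np.random.default_rng(1)
per_image = []
for k in range(40):
    n = int(rng.integers(1, 50))
    gt, _ = sample_ground_truth(
        SceneConfig(image_w=1000, image_h=1600, n_nodules=n, seed=100 + k))
    preds = mock_detect(gt, MockDetectorConfig(
        jitter_sd=1.0, fn_rate=0.10, fp_per_image=2.0,
        confidence_range=(0.3, 1.0), seed=100 + k))
    counts = match_detections(preds, gt.boxes)
    per_image.append((n,) + image_metrics(counts))

print(f"{'bin':>8} {'n':>3} {'precision':>10} {'recall':>8} {'f1':>8}")
for row in bin_report(per_image):
    print(f"{row.bin_label:>8} {row.n_images:>3} {row.mean_precision:>10.4f} "
          f"{row.mean_recall:>8.4f} {row.mean_f1:>8.4f}")
print("recall ~0.9 reflects the injected 10% miss rate; precision drops most "
      "in sparse bins where each spurious box weighs more.")
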