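import numpy as np
import pytest

from nodulescan.geometry import PixelBox


def random_boxes(rng, n, image_w=1000.0, image_h=1000.0, max_side=60.0):
    """n random boxes fully inside the image (not necessarily disjoint)."""
    out = []
    for _ in range(n):
        w = rng.uniform(2.0, max_side)
        h = rng.uniform(2.0, max_side)
        x0 = rng.uniform(0.0, image_w - w)
        y0 = rng.uniform(0.0, image_h - h)
        out.append(PixelBox(x0, y0, x0 + w, y0 + h))
    return out


def disjoint_boxes(rng, n, image_w=2000.0, image_h=2000.0, max_side=40.0,
                   gap=5.0, budget=10000):
    """n random pairwise-disjoint boxes separated by at least ``gap`` px."""
    out = []
    for _ in range(budget):
        if len(out) == n:
            break
        (cand,) = random_boxes(rng, 1, image_w, image_h, max_side)
        if all(cand.x_max + gap <= b.x_min or b.x_max + gap <= cand.x_min
               or cand.y_max + gap <= b.y_min or b.y_max + gap <= cand.y_min
               for b in out):
            out.append(cand)
    assert len(out) == n, "fixture packing failed"
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
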