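"""The 24-trait vector: worked examples, invariances, and order-stat oracle."""

import math

import numpy as np
import pytest

from nodulescan.geometry import Detection, PixelBox
from nodulescan.traits import TRAIT_NAMES, extract_traits
from .conftest import random_boxes


def centered_box(cx, cy, w=10.0, h=10.0):
    return PixelBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def test_schema_is_fixed_24_names():
    assert len(TRAIT_NAMES) == 24
    assert len(set(TRAIT_NAMES)) == 24
    assert TRAIT_NAMES[0] == "count"


@pytest.mark.parametrize("boxes", [
    [],
    [centered_box(100, 200)],
    [centered_box(100, 100), centered_box(200, 300), centered_box(300, 500)],
])
def test_always_emits_exactly_24_traits(boxes):
    traits = extract_traits(boxes)
    assert list(traits.keys()) == list(TRAIT_NAMES)


def test_empty_input():
    traits = extract_traits([])
    assert traits["count"] == 0
    assert all(math.isnan(traits[name]) for name in TRAIT_NAMES[1:])


def test_single_box():
    traits = extract_traits([centered_box(100, 200)])
    assert traits["count"] == 1
    assert traits["height"] == 0 and traits["width"] == 0
    assert traits["sdx"] == 0 and traits["sdy"] == 0
    assert math.isnan(traits["sdxy"])
    assert all(traits[f"box_area_{s}"] == 100 for s in
               ("min", "max", "mean", "median", "p5", "p25", "p75", "p95"))
    assert traits["box_area_std"] == 0
    assert traits["y_center_mean"] == 200 and traits["y_center_std"] == 0


def test_three_box_worked_example():
    """Hand-computed statistics for three 10x10 boxes at known centers."""
    boxes = [centered_box(100, 100), centered_box(200, 300), centered_box(300, 500)]
    t = extract_traits(boxes)
    assert t["count"] == 3
    assert t["height"] == pytest.approx(400, abs=1e-9)
    assert t["width"] == pytest.approx(200, abs=1e-9)
    assert t["sdx"] == pytest.approx(math.sqrt(20000 / 3), abs=1e-9)   # 81.6497
    assert t["sdy"] == pytest.approx(math.sqrt(80000 / 3), abs=1e-9)   # 163.299
    assert t["sdxy"] == pytest.approx(0.5, abs=1e-9)
    for s in ("min", "max", "mean", "median", "p5", "p25", "p75", "p95"):
        assert t[f"box_area_{s}"] == pytest.approx(100, abs=1e-9)
    assert t["box_area_std"] == pytest.approx(0, abs=1e-9)
    expected_y = {"min": 100, "p5": 120, "p25": 200, "median": 300, "mean": 300,
                  "p75": 400, "p95": 480, "max": 500}
    for s, v in expected_y.items():
        assert t[f"y_center_{s}"] == pytest.approx(v, abs=1e-9)
    assert t["y_center_std"] == pytest.approx(math.sqrt(80000 / 3), abs=1e-9)


def test_accepts_detections_and_boxes():
    boxes = [centered_box(50, 60), centered_box(80, 90)]
    dets = [Detection(b, 0.7) for b in boxes]
    assert extract_traits(dets) == extract_traits(boxes)


class TestInvariances:
    def test_translation(self, rng):
        for _ in range(40):
            boxes = random_boxes(rng, int(rng.integers(2, 30)))
            dx, dy = rng.uniform(-500, 500, size=2)
            base = extract_traits(boxes)
            shifted = extract_traits([b.translate(dx, dy) for b in boxes])
            for name in ("count", "height", "width", "sdx", "sdy", "sdxy"):
                assert shifted[name] == pytest.approx(base[name], abs=1e-6)
            for s in ("min", "max", "std", "mean", "median", "p5", "p25", "p75", "p95"):
                assert shifted[f"box_area_{s}"] == pytest.approx(
                    base[f"box_area_{s}"], abs=1e-6)
            for s in ("min", "max", "mean", "median", "p5", "p25", "p75", "p95"):
                assert shifted[f"y_center_{s}"] == pytest.approx(
                    base[f"y_center_{s}"] + dy, abs=1e-6)
            assert shifted["y_center_std"] == pytest.approx(
                base["y_center_std"], abs=1e-6)

    def test_scale_covariance(self, rng):
        for _ in range(40):
            boxes = random_boxes(rng, int(rng.integers(2, 30)))
            s = float(rng.uniform(0.2, 5.0))
            base = extract_traits(boxes)
            scaled = extract_traits([
                PixelBox(b.x_min * s, b.y_min * s, b.x_max * s, b.y_max * s)
                for b in boxes])
            assert scaled["count"] == base["count"]
            assert scaled["sdxy"] == pytest.approx(base["sdxy"], rel=1e-9)
            for name in ("height", "width", "sdx", "sdy"):
                assert scaled[name] == pytest.approx(base[name] * s, rel=1e-9)
            for st in ("min", "max", "std", "mean", "median", "p5", "p25", "p75", "p95"):
                assert scaled[f"box_area_{st}"] == pytest.approx(
                    base[f"box_area_{st}"] * s * s, rel=1e-9)
                assert scaled[f"y_center_{st}"] == pytest.approx(
                    base[f"y_center_{st}"] * s, rel=1e-9)

    def test_percentile_chain(self, rng):
        for _ in range(100):
            boxes = random_boxes(rng, int(rng.integers(1, 40)))
            t = extract_traits(boxes)
            for prefix in ("box_area", "y_center"):
                chain = [t[f"{prefix}_{s}"] for s in
                         ("min", "p5", "p25", "median", "p75", "p95", "max")]
                assert all(a <= b + 1e-12 for a, b in zip(chain, chain[1:]))


def oracle_nine_stats(values):
    """Independent order/moment statistics: explicit sort plus the
    closest-ranks linear-interpolation percentile formula."""
    v = sorted(values)
    n = len(v)

    def pct(p):
        h = (n - 1) * p / 100.0
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    mean = sum(v) / n
    return {"min": v[0], "max": v[-1],
            "std": math.sqrt(sum((x - mean) ** 2 for x in v) / n),
            "mean": mean, "median": pct(50), "p5": pct(5), "p25": pct(25),
            "p75": pct(75), "p95": pct(95)}


def test_order_statistics_match_brute_force_oracle(rng):
    for _ in range(1000):
        boxes = random_boxes(rng, int(rng.integers(1, 25)))
        t = extract_traits(boxes)
        areas = [b.area for b in boxes]
        ys = [b.center[1] for b in boxes]
        for prefix, values in (("box_area", areas), ("y_center", ys)):
            expected = oracle_nine_stats(values)
            for s, v in expected.items():
                assert t[f"{prefix}_{s}"] == pytest.approx(v, abs=1e-9 * max(1, abs(v)))
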