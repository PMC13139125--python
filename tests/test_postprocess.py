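"""Edge filtering, stitch-back translation, and greedy NMS."""

import pytest

from nodulescan.geometry import (Detection, FRAME_IMAGE, FRAME_PATCH,
                                 GeometryError, PixelBox, iou)
from nodulescan.postprocess import (PostprocessConfig, edge_filter, nms,
                                    refine_image, translate_to_global)
from nodulescan.tiler import plan_patches, remap_labels
from nodulescan.annotation_io import ImageAnnotationSet
from .conftest import random_boxes


def det(x0, y0, x1, y1, conf=0.9, frame=FRAME_PATCH):
    return Detection(PixelBox(x0, y0, x1, y1), conf, frame=frame)


def interior_spec():
    plan = plan_patches(2300, 4600, image_id="img")
    return plan, next(p for p in plan if (p.x0, p.y0) == (448, 896))


class TestEdgeFilter:
    def test_box_near_interior_edge_removed(self):
        plan, spec = interior_spec()
        kept = edge_filter([det(3, 100, 20, 120)], spec, 2300, 4600)
        assert kept == []

    def test_box_clear_of_edges_kept(self):
        plan, spec = interior_spec()
        kept = edge_filter([det(6, 6, 506, 506)], spec, 2300, 4600)
        assert len(kept) == 1

    def test_image_border_exemption(self):
        plan = plan_patches(2300, 4600, image_id="img")
        border = next(p for p in plan if (p.x0, p.y0) == (0, 896))
        kept = edge_filter([det(2, 100, 20, 120)], border, 2300, 4600)
        assert len(kept) == 1
        # with the exemption disabled the same detection is removed
        strict = PostprocessConfig(exempt_image_border=False)
        assert edge_filter([det(2, 100, 20, 120)], border, 2300, 4600, strict) == []

    def test_all_four_sides_checked(self):
        plan, spec = interior_spec()
        for box in [(100, 3, 120, 20), (100, 100, 509, 120), (100, 490, 120, 509)]:
            assert edge_filter([det(*box)], spec, 2300, 4600) == []

    def test_global_frame_rejected(self):
        plan, spec = interior_spec()
        with pytest.raises(GeometryError):
            edge_filter([det(50, 50, 60, 60, frame=FRAME_IMAGE)], spec, 2300, 4600)


class TestTranslate:
    def test_translation_example(self):
        plan, spec = interior_spec()
        (out,) = translate_to_global([det(10, 20, 30, 40)], spec)
        assert out.box.as_tuple() == (458, 916, 478, 936)
        assert out.frame == FRAME_IMAGE and out.confidence == 0.9

    def test_origin_zero_identity(self):
        plan = plan_patches(2300, 4600, image_id="img")
        origin = plan[0]
        (out,) = translate_to_global([det(10, 20, 30, 40)], origin)
        assert out.box.as_tuple() == (10, 20, 30, 40)

    def test_already_global_rejected(self):
        plan, spec = interior_spec()
        with pytest.raises(GeometryError):
            translate_to_global([det(1, 1, 2, 2, frame=FRAME_IMAGE)], spec)

    def test_round_trip_with_remap(self):
        """remap then translate reproduces an unclipped global box exactly."""
        plan, spec = interior_spec()
        gt = ImageAnnotationSet("img", 2300, 4600, [PixelBox(500, 950, 540, 990)])
        local = remap_labels(gt, spec)
        dets = [Detection(b, 1.0, frame=FRAME_PATCH) for b in local.boxes]
        (out,) = translate_to_global(dets, spec)
        assert out.box.as_tuple() == (500, 950, 540, 990)


class TestNms:
    def test_overlapping_pair_collapses(self):
        a = det(0, 0, 10, 10, 0.9, frame=FRAME_IMAGE)
        b = det(1, 1, 11, 11, 0.8, frame=FRAME_IMAGE)
        assert iou(a.box, b.box) == pytest.approx(81 / 119)
        kept = nms([b, a])
        assert kept == [a]

    def test_disjoint_pair_survives(self):
        a = det(0, 0, 10, 10, 0.9, frame=FRAME_IMAGE)
        b = det(50, 50, 60, 60, 0.8, frame=FRAME_IMAGE)
        assert nms([a, b]) == [a, b]

    def test_confidence_floor(self):
        low = det(0, 0, 10, 10, 0.15, frame=FRAME_IMAGE)
        assert nms([low]) == []

    def test_idempotent(self, rng):
        dets = [Detection(b, float(c), frame=FRAME_IMAGE) for b, c in
                zip(random_boxes(rng, 60, 300, 300), rng.uniform(0, 1, 60))]
        once = nms(dets)
        assert nms(once) == once

    def test_output_pairwise_iou_below_threshold(self, rng):
        config = PostprocessConfig()
        dets = [Detection(b, float(c), frame=FRAME_IMAGE) for b, c in
                zip(random_boxes(rng, 80, 300, 300), rng.uniform(0, 1, 80))]
        kept = nms(dets, config)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert iou(a.box, b.box) < config.nms_iou

    def test_monotone_in_thresholds(self, rng):
        dets = [Detection(b, float(c), frame=FRAME_IMAGE) for b, c in
                zip(random_boxes(rng, 80, 300, 300), rng.uniform(0, 1, 80))]
        base = len(nms(dets, PostprocessConfig(nms_confidence=0.2, nms_iou=0.2)))
        tighter_iou = len(nms(dets, PostprocessConfig(nms_confidence=0.2, nms_iou=0.1)))
        higher_conf = len(nms(dets, PostprocessConfig(nms_confidence=0.5, nms_iou=0.2)))
        assert tighter_iou <= base and higher_conf <= base

    def test_deterministic_tie_break(self):
        a = det(0, 0, 10, 10, 0.5, frame=FRAME_IMAGE)
        b = det(100, 0, 110, 10, 0.5, frame=FRAME_IMAGE)
        assert nms([b, a]) == [a, b]


class TestRefineImage:
    def test_overlap_duplicate_collapses_to_one(self):
        """A nodule inside the 64-px overlap band, seen by both patches, yields
        exactly one final detection."""
        plan = plan_patches(960, 512, image_id="img")
        left, right = plan
        gt = ImageAnnotationSet("img", 960, 512, [PixelBox(470, 200, 490, 220)])
        per_patch = []
        for spec in (left, right):
            local = remap_labels(gt, spec)
            per_patch.append((spec, [Detection(b, 1.0, frame=FRAME_PATCH)
                                     for b in local.boxes]))
        assert all(len(d) == 1 for _, d in per_patch)
        final = refine_image(per_patch, plan, 960, 512)
        assert len(final) == 1
        assert final[0].box.as_tuple() == (470, 200, 490, 220)

    def test_empty_input(self):
        plan = plan_patches(960, 512, image_id="img")
        assert refine_image([(p, []) for p in plan], plan, 960, 512) == []

    def test_unknown_patch_rejected(self):
        plan = plan_patches(960, 512, image_id="img")
        foreign = plan_patches(2300, 4600, image_id="other")[10]
        with pytest.raises(ValueError):
            refine_image([(foreign, [])], plan, 960, 512)

    def test_oracle_scene_recovered_exactly(self, rng):
        """Perfect per-patch oracle detections on separated nodules come back
        as exactly the ground truth after the full refinement chain."""
        from .conftest import disjoint_boxes
        boxes = disjoint_boxes(rng, 30, 2300, 4600, max_side=57, gap=10)
        gt = ImageAnnotationSet("img", 2300, 4600, boxes)
        plan = plan_patches(2300, 4600, image_id="img")
        per_patch = [(spec, [Detection(b, 1.0, frame=FRAME_PATCH)
                             for b in remap_labels(gt, spec).boxes])
                     for spec in plan]
        final = refine_image(per_patch, plan, 2300, 4600)
        assert len(final) == 30
        matched = {b.as_tuple() for b in boxes} & \
            {d.box.as_tuple() for d in final}
        assert len(matched) == 30
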