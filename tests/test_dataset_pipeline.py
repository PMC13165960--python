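"""YOLO TXT I/O, geometric augmentation, letterboxing, and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import AffineTransform, warp

from hueprior.dataset_pipeline import (CLASS_NAMES, DetectionLabel,
                                       LabelParseError, _transform_labels,
                                       augment_geometric, parse_yolo_line,
                                       read_yolo_labels, resize_to_canvas,
                                       split_dataset, write_yolo_labels)
from hueprior.evaluation import iou
from hueprior.synthetic_scenes import SceneSpec, render_scene


def random_labels(rng, n):
    labels = []
    for _ in range(n):
        w, h = rng.uniform(0.02, 0.3, size=2)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        labels.append(DetectionLabel(int(rng.integers(0, 5)), cx, cy, w, h))
    return labels


class TestYoloIO:
    def test_parse_known_line(self):
        lb = parse_yolo_line("2 0.5 0.5 0.1 0.2")
        assert lb.class_id == 2 and lb.class_name == "coral"
        assert (lb.cx, lb.cy, lb.w, lb.h) == (0.5, 0.5, 0.1, 0.2)

    def test_roundtrip_random(self, tmp_path, rng):
        labels = random_labels(rng, 20)
        path = tmp_path / "l.txt"
        write_yolo_labels(labels, path)
        loaded = read_yolo_labels(path)
        for a, b in zip(labels, loaded):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert read_yolo_labels(path) == []

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1 0.1\nnot a label\n")
        with pytest.raises(LabelParseError) as err:
            read_yolo_labels(path)
        assert err.value.line_no == 2

    def test_invalid_class_id(self):
        with pytest.raises(ValueError):
            DetectionLabel(5, 0.5, 0.5, 0.1, 0.1)

    def test_box_outside_unit_square(self):
        with pytest.raises(ValueError):
            DetectionLabel(0, 0.95, 0.5, 0.2, 0.1)

    def test_class_schema(self):
        assert CLASS_NAMES == ("base", "mulberry", "coral", "forming", "maturation")


class TestAugmentGeometric:
    def test_identity_transform(self, rng):
        image = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        labels = random_labels(rng, 4)
        out_img, out_labels = augment_geometric(
            image, labels, ["translate"], seed=0, max_translate=0.0)
        np.testing.assert_array_equal(out_img, image)
        for a, b in zip(labels, out_labels):
            assert a.cx == pytest.approx(b.cx) and a.w == pytest.approx(b.w)

    def test_pure_translation_shifts_centers(self):
        label = DetectionLabel(0, 0.5, 0.5, 0.2, 0.2)
        tform = AffineTransform(translation=(10, -6))
        out = _transform_labels([label], tform, width=100, height=100)
        assert out[0].cx == pytest.approx(0.6)
        assert out[0].cy == pytest.approx(0.44)
        assert out[0].w == pytest.approx(0.2) and out[0].h == pytest.approx(0.2)

    def test_right_angle_rotation_of_centered_square(self):
        label = DetectionLabel(1, 0.5, 0.5, 0.4, 0.4)
        center = np.array([50.0, 50.0])
        tform = (AffineTransform(translation=-center)
                 + AffineTransform(rotation=np.pi / 2)
                 + AffineTransform(translation=center))
        out = _transform_labels([label], tform, width=100, height=100)
        assert out[0].cx == pytest.approx(0.5) and out[0].cy == pytest.approx(0.5)
        assert out[0].w == pytest.approx(0.4) and out[0].h == pytest.approx(0.4)

    def test_clipped_boxes_dropped_below_area_floor(self):
        label = DetectionLabel(0, 0.05, 0.05, 0.1, 0.1)
        tform = AffineTransform(translation=(-9, -9))  # nearly off-canvas
        out = _transform_labels([label], tform, width=100, height=100)
        assert out == []

    def test_requires_ops(self, rng):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            augment_geometric(image, [], [], seed=0)
        with pytest.raises(ValueError):
            augment_geometric(image, [], ["shear"], seed=0)

    def test_no_photometric_change(self):
        """Geometric warps interpolate (convex-combine) existing values but
        never brighten, saturate, or add noise beyond the original range."""
        image = np.zeros((64, 64, 3), dtype=np.uint8)
        image[20:40, 20:40] = (200, 120, 40)
        out, _ = augment_geometric(image, [], ["translate", "rotate"], seed=1)
        for c in range(3):
            assert out[..., c].max() <= image[..., c].max()
            assert out[..., c].min() >= image[..., c].min()

    def test_box_tracks_pixels(self):
        """Transformed boxes stay tight on transformed object pixels
        (IoU >= 0.8 against the pixel-derived box)."""
        image, labels, debug = render_scene(
            SceneSpec(n_objects=4, seed=17, size_range=(60, 120)),
            return_debug=True)
        out_img, out_labels = augment_geometric(image, labels, ["translate", "scale"],
                                                seed=3)
        # recompute the same transform for the masks
        rng = np.random.default_rng(3)
        tx = rng.uniform(-0.2, 0.2) * 640
        ty = rng.uniform(-0.2, 0.2) * 640
        scale = rng.uniform(0.8, 1.2)
        center = np.array([320.0, 320.0])
        tform = (AffineTransform(translation=-center)
                 + AffineTransform(scale=scale)
                 + AffineTransform(translation=center)
                 + AffineTransform(translation=(tx, ty)))
        kept = 0
        for mask, label in zip(debug.object_masks, labels):
            warped_mask = warp(mask.astype(float), tform.inverse,
                               output_shape=mask.shape, order=0) > 0.5
            if not warped_mask.any():
                continue
            ys, xs = np.nonzero(warped_mask)
            pixel_box = (xs.min() / 640, ys.min() / 640,
                         (xs.max() + 1) / 640, (ys.max() + 1) / 640)
            matches = [lb for lb in out_labels if lb.class_id == label.class_id]
            if not matches:
                continue
            best = max(iou(pixel_box, lb.corners()) for lb in matches)
            assert best >= 0.8
            kept += 1
        assert kept >= 2  # the check must actually exercise objects


class TestResizeToCanvas:
    def test_uniform_downscale_keeps_labels(self, rng):
        image = rng.integers(0, 255, size=(1280, 1280, 3), dtype=np.uint8)
        labels = random_labels(rng, 3)
        out, out_labels = resize_to_canvas(image, labels, side=640)
        assert out.shape == (640, 640, 3)
        assert out_labels == labels

    def test_letterbox_formula(self):
        image = np.full((200, 400, 3), 255, dtype=np.uint8)
        label = DetectionLabel(0, 0.5, 0.5, 0.5, 0.5)
        out, out_labels = resize_to_canvas(image, [label], side=640)
        assert out.shape == (640, 640, 3)
        # scale 640/400 = 1.6 -> content 320x640, pad_y = 160
        lb = out_labels[0]
        assert lb.cx == pytest.approx(0.5)
        assert lb.cy == pytest.approx((0.5 * 320 + 160) / 640)
        assert lb.w == pytest.approx(0.5)
        assert lb.h == pytest.approx(0.5 * 320 / 640)
        # padding rows are black
        assert not out[:160].any() and not out[-160:].any()

    def test_already_sized_untouched(self, rng):
        image = rng.integers(0, 255, size=(640, 640, 3), dtype=np.uint8)
        out, _ = resize_to_canvas(image, [], side=640)
        np.testing.assert_array_equal(out, image)


class TestSplitDataset:
    def test_hundred_ids_split_80_10_10(self):
        split = split_dataset([f"i{k}" for k in range(100)], (8, 1, 1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (80, 10, 10)

    def test_ten_ids_split_8_1_1(self):
        split = split_dataset([f"i{k}" for k in range(10)], (8, 1, 1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)

    def test_same_seed_same_split(self):
        ids = [f"i{k}" for k in range(37)]
        a = split_dataset(ids, seed=5)
        b = split_dataset(ids, seed=5)
        assert a.as_dict() == b.as_dict()
        c = split_dataset(ids, seed=6)
        assert a.as_dict() != c.as_dict()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"], seed=0)
        with pytest.raises(ValueError):
            split_dataset(["a", "b", "c"], ratios=(1, 0, 1), seed=0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(3, 400), seed=st.integers(0, 10**6))
    def test_disjoint_and_covering(self, n, seed):
        ids = [f"id{k}" for k in range(n)]
        split = split_dataset(ids, seed=seed)
        merged = split.train + split.val + split.test
        assert sorted(merged) == sorted(ids)
        assert len(set(split.train) & set(split.val)) == 0
        assert len(set(split.val) & set(split.test)) == 0
        assert len(set(split.train) & set(split.test)) == 0
        # realized counts within one item of the exact ratios
        for part, ratio in zip((split.train, split.val, split.test), (8, 1, 1)):
            assert abs(len(part) - n * ratio / 10) < 1
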