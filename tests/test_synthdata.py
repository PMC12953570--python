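"""Scene generator determinism and geometry, label I/O, split arithmetic."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beamyolo.synthdata import (BoxAnnotation, SceneSpec, SplitSpec,
                                generate_scene, read_yolo_labels,
                                split_dataset, split_sizes, write_yolo_labels)


class TestSceneGeneration:
    def test_seeded_determinism(self):
        spec = SceneSpec(image_size=160, num_classes=5, seed=42,
                         object_size_px=(10, 40))
        img1, ann1 = generate_scene(spec)
        img2, ann2 = generate_scene(spec)
        np.testing.assert_array_equal(img1, img2)
        assert ann1 == ann2

    def test_zero_objects_gives_background_only(self):
        spec = SceneSpec(image_size=128, objects_per_image=(0, 0), seed=3,
                         object_size_px=(10, 30))
        img, anns = generate_scene(spec)
        assert anns == []
        assert img.shape == (128, 128, 3)
        assert img.min() >= 0 and img.max() <= 1

    def test_annotation_geometry_matches_requested_size(self):
        # class 0 renders circles; a fixed 20 px diameter on a 640 scene
        # must yield boxes of ~20/640 normalized extent
        spec = SceneSpec(image_size=640, num_classes=11,
                         objects_per_image=(5, 5), object_size_px=(20, 20),
                         contrast="high", seed=11)
        _, anns = generate_scene(spec)
        assert len(anns) == 5
        for a in anns:
            if a.class_id == 0:  # aspect exactly 1: circle of diameter 20
                assert a.w * 640 == pytest.approx(20, abs=2)
                assert a.h * 640 == pytest.approx(20, abs=2)

    def test_annotations_satisfy_box_invariants(self):
        spec = SceneSpec(image_size=320, objects_per_image=(4, 8),
                         object_size_px=(10, 60), seed=7)
        _, anns = generate_scene(spec)
        for a in anns:
            x0, y0, x1, y1 = a.corners()
            assert 0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1
            assert 0 <= a.class_id < 11

    def test_low_contrast_objects_are_close_to_background(self):
        base = dict(image_size=160, objects_per_image=(3, 3),
                    object_size_px=(20, 30), seed=5)
        img_hi, ann_hi = generate_scene(SceneSpec(contrast="high", **base))
        img_lo, ann_lo = generate_scene(SceneSpec(contrast="low", **base))

        def mean_object_bg_distance(img, anns):
            dists = []
            bg = np.median(img.reshape(-1, 3), axis=0)
            for a in anns:
                x0, y0, x1, y1 = (np.array(a.corners()) * 160).astype(int)
                patch = img[y0:y1, x0:x1].reshape(-1, 3).mean(axis=0)
                dists.append(np.linalg.norm(patch - bg))
            return np.mean(dists)

        assert (mean_object_bg_distance(img_lo, ann_lo)
                < mean_object_bg_distance(img_hi, ann_hi))

    def test_infeasible_packing_raises(self):
        spec = SceneSpec(image_size=96, objects_per_image=(60, 60),
                         object_size_px=(40, 60), seed=0)
        with pytest.raises(RuntimeError, match="too crowded"):
            generate_scene(spec)


class TestYoloLabels:
    def test_exact_line_format(self, tmp_path):
        p = tmp_path / "a.txt"
        write_yolo_labels([BoxAnnotation(3, 0.5, 0.5, 0.1, 0.2)], p)
        assert p.read_text() == "3 0.500000 0.500000 0.100000 0.200000\n"

    def test_empty_list_gives_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        write_yolo_labels([], p)
        assert p.read_text() == ""
        assert read_yolo_labels(p) == []

    def test_round_trip_fuzz(self, tmp_path, rng):
        anns = []
        for _ in range(1000):
            w, h = rng.uniform(0.01, 0.5, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            anns.append(BoxAnnotation(int(rng.integers(11)), cx, cy, w, h))
        p = tmp_path / "fuzz.txt"
        write_yolo_labels(anns, p)
        back = read_yolo_labels(p)
        assert len(back) == len(anns)
        for a, b in zip(anns, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert abs(getattr(a, f) - getattr(b, f)) <= 5e-7

    @pytest.mark.parametrize("line,msg", [
        ("1 0.5 0.5 0.1", "5 fields"),
        ("x 0.5 0.5 0.1 0.1", "unparsable"),
        ("1 0.5 0.5 0.0 0.1", "size"),
        ("1 0.99 0.5 0.1 0.1", "outside"),
    ])
    def test_malformed_lines_report_line_number(self, tmp_path, line, msg):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.500000 0.500000 0.100000 0.100000\n" + line + "\n")
        with pytest.raises(ValueError, match=f"(?s)bad.txt.*2.*{msg}"):
            read_yolo_labels(p)


class TestSplits:
    def test_reference_split_arithmetic(self):
        assert split_sizes(4565, (8, 1, 1)) == (3652, 456, 457)

    def test_exact_divisibility(self):
        assert split_sizes(10, (8, 1, 1)) == (8, 1, 1)

    @given(st.integers(3, 5000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_property(self, n):
        train, val, test = split_dataset(n, SplitSpec((8, 1, 1), seed=9))
        allidx = np.concatenate([train, val, test])
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n
        for part, ratio in zip((train, val, test), (0.8, 0.1, 0.1)):
            assert abs(len(part) - n * ratio) < 1 + 1e-9

    def test_reproducible_across_calls(self):
        a = split_dataset(100, SplitSpec(seed=5))
        b = split_dataset(100, SplitSpec(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_stratified_mode_balances_labels(self):
        labels = np.repeat(np.arange(5), 20)
        train, val, test = split_dataset(100, SplitSpec((8, 1, 1), seed=1),
                                         labels=labels)
        for lab in range(5):
            assert np.sum(labels[train] == lab) == 16

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="partitions"):
            split_dataset(2, SplitSpec((8, 1, 1)))
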