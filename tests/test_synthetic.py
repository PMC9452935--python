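"""Synthetic generator, augmentation, expansion and split protocol."""

import dataclasses
import math

import numpy as np
import pytest

from wbcseg import (AugmentationSpec, SceneConfig, augment, expand_dataset,
                    generate_cell_image, generate_dataset, load_dataset,
                    save_dataset, split_dataset)


class TestGenerator:
    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(side=64, seed=42)
        i1, m1 = generate_cell_image(cfg)
        i2, m2 = generate_cell_image(cfg)
        assert (i1 == i2).all() and (m1 == m2).all()

    def test_different_seeds_differ(self):
        i1, m1 = generate_cell_image(SceneConfig(side=64, seed=0))
        i2, m2 = generate_cell_image(SceneConfig(side=64, seed=1))
        assert not (m1 == m2).all()

    def test_output_types_and_ranges(self):
        img, mask = generate_cell_image(SceneConfig(side=64, seed=7))
        assert img.shape == (64, 64, 3) and img.dtype == np.float32
        assert mask.shape == (64, 64) and set(np.unique(mask)) <= {0, 1}
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_foreground_fraction_within_radius_bounds(self):
        """Cell area stays within the generating-ellipse bounds
        [pi 0.15^2, pi 0.35^2] of the canvas (20 seeds, small discretization
        slack)."""
        lo, hi = math.pi * 0.15 ** 2, math.pi * 0.35 ** 2
        for seed in range(20):
            _, mask = generate_cell_image(SceneConfig(side=128, seed=seed))
            frac = mask.mean()
            assert lo * 0.9 <= frac <= hi * 1.1, (seed, frac)

    def test_zero_irregularity_gives_exact_ellipse(self):
        cfg = SceneConfig(side=96, boundary_irregularity=0.0, seed=3)
        _, mask, scene = generate_cell_image(cfg, return_scene=True)
        (cy, cx), (a, b) = scene["center"], scene["axes"]
        ang = scene["angle"]
        yy, xx = np.mgrid[0:96, 0:96]
        u = (xx - cx) * math.cos(ang) + (yy - cy) * math.sin(ang)
        v = -(xx - cx) * math.sin(ang) + (yy - cy) * math.cos(ang)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        assert (mask.astype(bool) == inside).all()

    def test_degenerate_radius_range_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(cell_radius_range=(0.3, 0.2))
        with pytest.raises(ValueError):
            SceneConfig(cell_radius_range=(0.0, 0.3))

    def test_hardness_dial_monotone_boundary_contrast(self):
        """Lower color_proximity -> lower mean absolute intensity step
        across the mask boundary, for each of 10 paired seeds."""
        from scipy import ndimage

        def boundary_contrast(cfg):
            img, mask = generate_cell_image(cfg)
            gray = img.mean(axis=2)
            m = mask.astype(bool)
            outer = ndimage.binary_dilation(m, iterations=2) & ~m
            inner = m & ~ndimage.binary_erosion(m, iterations=2)
            return abs(gray[inner].mean() - gray[outer].mean())

        for seed in range(10):
            hard = boundary_contrast(SceneConfig(side=64, seed=seed,
                                                 color_proximity=0.05))
            easy = boundary_contrast(SceneConfig(side=64, seed=seed,
                                                 color_proximity=0.35))
            assert hard < easy, (seed, hard, easy)

    def test_generate_dataset_deterministic_and_distinct(self):
        cfg = SceneConfig(side=48, seed=5)
        d1 = generate_dataset(cfg, 4)
        d2 = generate_dataset(cfg, 4)
        for (i1, m1), (i2, m2) in zip(d1, d2):
            assert (i1 == i2).all() and (m1 == m2).all()
        assert not (d1[0][1] == d1[1][1]).all()


class TestAugment:
    @pytest.fixture
    def pair(self):
        return generate_cell_image(SceneConfig(side=48, seed=9))

    def test_hflip_is_involution(self, pair):
        img, mask = pair
        spec = AugmentationSpec(ops=(("hflip", {"p": 1.0}),), seed=0)
        i1, m1 = augment(img, mask, spec)
        i2, m2 = augment(i1, m1, spec)
        assert (i2 == img).all() and (m2 == mask).all()

    def test_right_angle_rotation_preserves_mask_area(self, pair):
        img, mask = pair
        spec = AugmentationSpec(ops=(("rotate", {"degrees": (90.0, 90.0)}),),
                                seed=0)
        _, m = augment(img, mask, spec)
        assert m.sum() == mask.sum()

    def test_photometric_ops_leave_mask_bit_identical(self, pair):
        img, mask = pair
        spec = AugmentationSpec(ops=(("brightness", {"range": (0.5, 0.6)}),
                                     ("contrast", {"range": (1.3, 1.4)})),
                                seed=0)
        i, m = augment(img, mask, spec)
        assert (m == mask).all()
        assert not (i == img).all()

    def test_scale_keeps_canvas_size_and_binary_mask(self, pair):
        img, mask = pair
        spec = AugmentationSpec(ops=(("scale", {"range": (1.2, 1.2)}),), seed=0)
        i, m = augment(img, mask, spec)
        assert i.shape == img.shape and m.shape == mask.shape
        assert set(np.unique(m)) <= {0, 1}

    def test_seeded_determinism(self, pair):
        img, mask = pair
        spec = AugmentationSpec(seed=123)
        a = augment(img, mask, spec)
        b = augment(img, mask, spec)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation"):
            AugmentationSpec(ops=(("shear", {}),))


class TestExpandAndSplit:
    def test_round_robin_balance(self):
        pairs = generate_dataset(SceneConfig(side=32, seed=1), 7)
        items = expand_dataset(pairs, 25, AugmentationSpec(seed=0))
        assert len(items) == 25
        counts = np.bincount([it["source_index"] for it in items], minlength=7)
        assert set(counts.tolist()) <= {math.floor(25 / 7), math.ceil(25 / 7)}
        assert all(set(np.unique(it["mask"])) <= {0, 1} for it in items)

    def test_target_equals_input_returns_originals(self):
        pairs = generate_dataset(SceneConfig(side=32, seed=2), 3)
        items = expand_dataset(pairs, 3)
        for (img, mask), it in zip(pairs, items):
            assert (it["image"] == img).all() and (it["mask"] == mask).all()
            assert it["ops"] == ()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expand_dataset([], 10)

    def test_provenance_recorded(self):
        pairs = generate_dataset(SceneConfig(side=32, seed=3), 2)
        items = expand_dataset(pairs, 5, AugmentationSpec(seed=4))
        augmented = [it for it in items if it["augment_seed"] is not None]
        assert len(augmented) == 3
        assert all(it["ops"] for it in augmented)

    def test_split_8_1_1(self):
        tr, va, te = split_dataset(list(range(10)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        tr, va, te = split_dataset(list(range(1000)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_split_disjoint_and_exhaustive(self):
        items = list(range(103))
        parts = split_dataset(items, (8, 1, 1), seed=7)
        merged = [x for part in parts for x in part]
        assert sorted(merged) == items
        assert sum(len(p) for p in parts) == 103

    def test_split_seed_changes_assignment_not_sizes(self):
        a = split_dataset(list(range(50)), (8, 1, 1), seed=0)
        b = split_dataset(list(range(50)), (8, 1, 1), seed=1)
        assert [len(p) for p in a] == [len(p) for p in b]
        assert any(set(pa) != set(pb) for pa, pb in zip(a, b))

    def test_split_errors(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], (8, 1, 1), seed=0)
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (1, 0, 1), seed=0)


class TestDiskLayout:
    def test_png_round_trip_with_manifest(self, tmp_path):
        pairs = generate_dataset(SceneConfig(side=32, seed=6), 2)
        items = expand_dataset(pairs, 4, AugmentationSpec(seed=1))
        save_dataset(tmp_path / "ds", items, splits={0: "train", 1: "train",
                                                     2: "val", 3: "test"})
        loaded, manifest = load_dataset(tmp_path / "ds")
        assert len(loaded) == 4
        assert manifest["splits"]["2"] == "val"
        for orig, back in zip(items, loaded):
            assert (orig["mask"] == back["mask"]).all()
            # 8-bit PNG quantization: images match to 1/255
            assert np.abs(orig["image"] - back["image"]).max() <= (1 / 255) + 1e-6
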