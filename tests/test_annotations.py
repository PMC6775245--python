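"""VIA parsing, patch construction, augmentation, and the train/val split."""

import json

import numpy as np
import pytest

from earcount.annotations import (
    AnnotatedShape,
    AugmentParams,
    Patch,
    PatchSet,
    augment,
    build_patches,
    read_via_annotations,
    split_train_val,
)


def via_project(tmp_path, regions_by_image):
    """Write a minimal VIA project JSON and return its path."""
    meta = {}
    for name, regions in regions_by_image.items():
        meta[f"{name}-1"] = {"filename": name, "size": -1, "regions": regions}
    path = tmp_path / "via.json"
    path.write_text(json.dumps({"_via_img_metadata": meta}))
    return path


def polygon_region(xs, ys, label="ear"):
    return {
        "shape_attributes": {"name": "polygon", "all_points_x": xs, "all_points_y": ys},
        "region_attributes": {"class": label},
    }


def rect_region(x, y, w, h, label="background"):
    return {
        "shape_attributes": {"name": "rect", "x": x, "y": y, "width": w, "height": h},
        "region_attributes": {"class": label},
    }


class TestViaParsing:
    def test_single_ear_polygon(self, tmp_path):
        path = via_project(tmp_path, {"a.png": [polygon_region([1, 8, 4], [1, 1, 8])]})
        shapes = read_via_annotations(path)
        assert len(shapes) == 1
        s = shapes[0]
        assert s.kind == "polygon" and s.class_label == "ear" and len(s.vertices) == 3

    def test_empty_regions_yield_empty_list(self, tmp_path):
        path = via_project(tmp_path, {"a.png": []})
        assert read_via_annotations(path) == []

    def test_mixed_rect_and_polygon_counts(self, tmp_path):
        path = via_project(tmp_path, {
            "a.png": [polygon_region([1, 6, 3], [1, 1, 6]), rect_region(0, 0, 4, 4)],
            "b.png": [rect_region(2, 2, 5, 5)],
        })
        shapes = read_via_annotations(path)
        assert len(shapes) == 3
        kinds = sorted(s.kind for s in shapes)
        assert kinds == ["box", "box", "polygon"]
        box = next(s for s in shapes if s.image_id == "b.png")
        assert box.vertices == [(2.0, 2.0), (7.0, 7.0)]

    def test_unknown_class_skipped(self, tmp_path):
        path = via_project(tmp_path, {
            "a.png": [polygon_region([1, 6, 3], [1, 1, 6], label="weed")],
        })
        assert read_via_annotations(path) == []

    def test_malformed_record_names_offender(self, tmp_path):
        path = via_project(tmp_path, {
            "bad.png": [{"shape_attributes": {"name": "polygon"},
                         "region_attributes": {"class": "ear"}}],
        })
        with pytest.raises(ValueError, match="bad.png"):
            read_via_annotations(path)

    def test_list_dialect_accepted(self, tmp_path):
        data = [{"filename": "a.png", "regions": [rect_region(0, 0, 3, 3)]}]
        path = tmp_path / "list.json"
        path.write_text(json.dumps(data))
        assert len(read_via_annotations(path)) == 1


class TestBuildPatches:
    @staticmethod
    def image(h=20, w=20):
        rng = np.random.default_rng(0)
        return rng.integers(0, 256, (h, w, 3), dtype=np.uint8)

    def test_square_polygon_fills_its_box(self):
        img = self.image()
        shape = AnnotatedShape("a", "polygon",
                               [(4, 4), (12, 4), (12, 12), (4, 12)], "ear")
        pset = build_patches({"a": img}, [shape], margin=0.0)
        patch = pset[0]
        # interior of the rasterized square covers the box up to its boundary row
        assert patch.mask.mean() > 0.85

    def test_background_box_has_zero_mask(self):
        shape = AnnotatedShape("a", "box", [(2, 3), (10, 9)], "background")
        pset = build_patches({"a": self.image()}, [shape])
        patch = pset[0]
        assert patch.class_label == "background"
        assert not patch.mask.any()
        assert patch.image.shape == (6, 3 + 5, 3)  # (y: 3..9, x: 2..10)

    def test_triangle_mask_matches_point_in_polygon_oracle(self):
        img = self.image()
        tri = [(1, 1), (9, 1), (1, 9)]
        pset = build_patches({"a": img}, [AnnotatedShape("a", "polygon", tri, "ear")],
                             margin=0.0)
        mask = pset[0].mask
        # oracle: a pixel center is inside the triangle x+y <= 10, x,y >= 1
        oracle = np.zeros_like(mask)
        for y in range(mask.shape[0]):
            for x in range(mask.shape[1]):
                if x >= 0 and y >= 0 and (x + 1) + (y + 1) <= 10:
                    oracle[y, x] = 1
        # rasterization may differ along the hypotenuse by one boundary row
        assert (mask != oracle).sum() <= mask.shape[0] + mask.shape[1]
        assert abs(int(mask.sum()) - int(oracle.sum())) <= mask.shape[0]

    def test_out_of_bounds_shape_clipped_with_warning(self):
        shape = AnnotatedShape("a", "box", [(-5, -5), (10, 10)], "background")
        with pytest.warns(UserWarning):
            pset = build_patches({"a": self.image()}, [shape])
        assert pset[0].image.shape == (10, 10, 3)

    def test_unknown_image_rejected(self):
        shape = AnnotatedShape("missing", "box", [(0, 0), (5, 5)], "background")
        with pytest.raises(KeyError):
            build_patches({}, [shape])


def blob_patch(size=24):
    """Patch whose mask equals `red channel > 128`, dark near the borders."""
    img = np.zeros((size, size, 3), np.uint8)
    img[...] = (30, 60, 30)
    img[8:16, 6:18] = (220, 180, 60)
    mask = (img[..., 0] > 128).astype(np.uint8)
    return Patch(img, mask, "ear")


class TestAugment:
    def test_all_zero_ranges_is_identity(self):
        params = AugmentParams(
            apply_probability=1.0, rotation_range=0.0, zoom_range=(1.0, 1.0),
            brightness_range=(1.0, 1.0), hue_shift=0.0,
            saturation_range=(1.0, 1.0), value_range=(1.0, 1.0),
            gamma_range=(1.0, 1.0), flip_horizontal=False, flip_vertical=False,
        )
        patch = blob_patch()
        out = augment(patch, params, np.random.default_rng(0))
        assert np.array_equal(out.image, patch.image)
        assert np.array_equal(out.mask, patch.mask)

    def test_geometry_preserves_image_mask_correspondence(self):
        # geometric transforms only; the mask must keep tracking the channel
        params = AugmentParams(
            apply_probability=1.0, rotation_range=25.0, zoom_range=(0.85, 1.15),
            brightness_range=(1.0, 1.0), hue_shift=0.0,
            saturation_range=(1.0, 1.0), value_range=(1.0, 1.0),
            gamma_range=(1.0, 1.0),
        )
        for seed in range(5):
            out = augment(blob_patch(), params, np.random.default_rng(seed))
            derived = (out.image[..., 0] > 128).astype(np.uint8)
            # interpolation can disagree on a thin boundary ring only
            assert (out.mask != derived).mean() < 0.05

    def test_flips_are_exact_involutions(self):
        params = AugmentParams(
            apply_probability=1.0, rotation_range=0.0, zoom_range=(1.0, 1.0),
            brightness_range=(1.0, 1.0), hue_shift=0.0,
            saturation_range=(1.0, 1.0), value_range=(1.0, 1.0),
            gamma_range=(1.0, 1.0), flip_horizontal=True, flip_vertical=False,
        )
        patch = blob_patch()
        once = augment(patch, params, np.random.default_rng(1))
        twice = augment(once, params, np.random.default_rng(1))
        assert np.array_equal(twice.image, patch.image)
        assert np.array_equal(twice.mask, patch.mask)

    def test_seeded_augmentation_is_reproducible(self):
        params = AugmentParams()
        a = augment(blob_patch(), params, np.random.default_rng(123))
        b = augment(blob_patch(), params, np.random.default_rng(123))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert a.class_label == b.class_label

    def test_ear_patch_never_loses_its_mask(self):
        params = AugmentParams(apply_probability=1.0, rotation_range=180.0,
                               zoom_range=(0.5, 2.0))
        for seed in range(20):
            out = augment(blob_patch(), params, np.random.default_rng(seed))
            assert out.mask.any()


class TestSplit:
    @staticmethod
    def patchset(n):
        patches = [blob_patch() for _ in range(n)]
        return PatchSet(patches)

    def test_sizes_follow_rounded_fraction(self):
        train, val = split_train_val(self.patchset(10), 0.2, seed=0)
        assert len(val) == 2 and len(train) == 8

    def test_split_is_a_partition(self):
        pset = self.patchset(13)
        train, val = split_train_val(pset, 0.3, seed=1)
        ids = {id(p) for p in pset}
        got = [id(p) for p in train] + [id(p) for p in val]
        assert sorted(got) == sorted(ids)

    def test_same_seed_same_split(self):
        pset = self.patchset(9)
        a = split_train_val(pset, 0.2, seed=5)
        b = split_train_val(pset, 0.2, seed=5)
        assert [id(p) for p in a[0]] == [id(p) for p in b[0]]

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(self.patchset(1), 0.2, seed=0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_train_val(self.patchset(5), frac, seed=0)


def test_patchset_disk_cache_round_trip(tmp_path):
    from earcount.annotations import load_patchset, save_patchset

    ear = blob_patch()
    bg = Patch(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), np.uint8), "background")
    pset = PatchSet([ear, bg])
    save_patchset(tmp_path / "cache", pset)
    assert (tmp_path / "cache" / "manifest.csv").exists()
    loaded = load_patchset(tmp_path / "cache")
    assert len(loaded) == 2
    for orig, back in zip(pset, loaded):
        assert np.array_equal(orig.image, back.image)
        assert np.array_equal(orig.mask, back.mask)
        assert orig.class_label == back.class_label


def test_patchset_class_counts():
    ear = blob_patch()
    bg = Patch(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), np.uint8), "background")
    pset = PatchSet([ear, bg, bg])
    assert pset.class_counts == {"ear": 1, "background": 2}
    with pytest.raises(ValueError):
        PatchSet([])
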