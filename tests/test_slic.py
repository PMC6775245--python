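"""Superpixel partitioning: seeding, k-means equivalence, connectivity, regions."""

import numpy as np
import pytest
from skimage import measure

from earcount.imaging import to_cielab
from earcount.slic import (
    RegionInput,
    SlicParams,
    enforce_connectivity,
    extract_regions,
    initialize_centers,
    slic_segment,
)


def uniform_image(h, w, color=(120, 120, 120)):
    img = np.zeros((h, w, 3), np.uint8)
    img[...] = color
    return img


def two_tone(h, w, split, axis=1, c1=(200, 30, 30), c2=(30, 30, 200)):
    img = np.zeros((h, w, 3), np.uint8)
    img[...] = c1
    if axis == 1:
        img[:, split:] = c2
    else:
        img[split:] = c2
    return img


def global_kmeans_oracle(img, params):
    """Unwindowed 5-D k-means from the same seeding: full-distance argmin
    assignment (first-minimum tie-break), mean update, fixed iterations."""
    lab = to_cielab(img)
    H, W = lab.shape[:2]
    S = np.sqrt(H * W / params.n_superpixels)
    w2 = (params.compactness / S) ** 2
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    centers = initialize_centers(lab, params).copy()
    feats = np.stack([lab[..., 0], lab[..., 1], lab[..., 2], xx, yy], axis=-1)
    labels = None
    for _ in range(params.max_iterations):
        d = (
            (feats[..., None, 0] - centers[:, 0]) ** 2
            + (feats[..., None, 1] - centers[:, 1]) ** 2
            + (feats[..., None, 2] - centers[:, 2]) ** 2
            + w2 * ((feats[..., None, 3] - centers[:, 3]) ** 2
                    + (feats[..., None, 4] - centers[:, 4]) ** 2)
        )
        labels = d.argmin(axis=-1)
        for k in range(len(centers)):
            sel = labels == k
            if sel.any():
                centers[k] = feats[sel].mean(axis=0)
    return labels.astype(np.int32)


class TestInitialization:
    def test_four_seeds_sit_on_the_grid(self):
        img = uniform_image(10, 10)
        centers = initialize_centers(to_cielab(img), SlicParams(n_superpixels=4))
        got = sorted((round(x), round(y)) for _, _, _, x, y in centers)
        # grid positions (2.5, 2.5) ... snapped to pixels, +-1 for perturbation
        expect = [(2, 2), (2, 7), (7, 2), (7, 7)]
        for (gx, gy), (ex, ey) in zip(got, expect):
            assert abs(gx - ex) <= 1 and abs(gy - ey) <= 1

    def test_one_seed_per_pixel_in_the_degenerate_grid(self):
        img = uniform_image(4, 4)
        centers = initialize_centers(to_cielab(img), SlicParams(n_superpixels=16))
        pts = {(int(x), int(y)) for _, _, _, x, y in centers}
        assert len(pts) == 16

    def test_uniform_image_keeps_grid_up_to_tiebreak(self):
        img = uniform_image(12, 12)
        params = SlicParams(n_superpixels=4)
        centers = initialize_centers(to_cielab(img), params)
        for _, _, _, x, y in centers:
            # zero gradient everywhere: perturbation moves at most 1 pixel
            assert min(abs(x - gx) for gx in (3, 9)) <= 1
            assert min(abs(y - gy) for gy in (3, 9)) <= 1

    def test_too_many_superpixels_rejected(self):
        with pytest.raises(ValueError):
            initialize_centers(to_cielab(uniform_image(4, 4)), SlicParams(n_superpixels=17))


class TestSegmentation:
    def test_output_is_a_partition_of_connected_regions(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        labels = slic_segment(img, SlicParams(n_superpixels=9))
        K = labels.max() + 1
        assert set(np.unique(labels)) == set(range(K))
        total = 0
        for k in range(K):
            comp = measure.label(labels == k, connectivity=1)
            assert comp.max() == 1  # 4-connected
            total += int((labels == k).sum())
        assert total == 1600

    def test_uniform_image_high_compactness_gives_near_square_cells(self):
        labels = slic_segment(
            uniform_image(64, 64), SlicParams(n_superpixels=16, compactness=1e6)
        )
        sizes = np.bincount(labels.ravel())
        assert len(sizes) == 16
        assert (np.abs(sizes - 256) <= 0.2 * 256).all()

    def test_two_tone_halves_recovered_with_two_superpixels(self):
        img = two_tone(12, 12, split=6)
        labels = slic_segment(img, SlicParams(n_superpixels=2))
        left = np.unique(labels[:, :6])
        right = np.unique(labels[:, 6:])
        assert len(left) == 1 and len(right) == 1 and left[0] != right[0]

    # cases chosen so 2S >= image size: there the windowed search degenerates
    # to a global one and localized SLIC must agree with plain 5-D k-means
    @pytest.mark.parametrize("shape,n", [((12, 12), 2), ((16, 16), 3), ((14, 16), 3)])
    def test_matches_global_kmeans_on_small_images(self, shape, n):
        rng = np.random.default_rng(shape[0] * n)
        img = rng.integers(0, 256, shape + (3,), dtype=np.uint8)
        params = SlicParams(n_superpixels=n)
        mine = slic_segment(img, params, enforce=False)
        oracle = global_kmeans_oracle(img, params)
        assert np.array_equal(mine, oracle)

    @staticmethod
    def _boundary_recall(labels, edge_dist):
        horiz = labels[:, 1:] != labels[:, :-1]
        vert = labels[1:, :] != labels[:-1, :]
        pts = []
        rr, cc = np.nonzero(horiz)
        pts += [(r, c + 0.5) for r, c in zip(rr, cc)]
        rr, cc = np.nonzero(vert)
        pts += [(r + 0.5, c) for r, c in zip(rr, cc)]
        assert pts, "segmentation produced no boundary at all"
        d = np.asarray([edge_dist(r, c) for r, c in pts])
        return (np.abs(d) <= 1.0).mean()

    def test_boundary_adherence_on_two_tone_edges(self):
        # vertical edge in a square image
        img = two_tone(64, 64, split=32)
        labels = slic_segment(img, SlicParams(n_superpixels=2))
        assert self._boundary_recall(labels, lambda r, c: c - 31.5) >= 0.95
        # horizontal edge in a tall image (seeding brackets the edge)
        img = two_tone(64, 32, split=32, axis=0)
        labels = slic_segment(img, SlicParams(n_superpixels=2))
        assert self._boundary_recall(labels, lambda r, c: r - 31.5) >= 0.95
        # diagonal edge
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.zeros((64, 64, 3), np.uint8)
        img[...] = (200, 30, 30)
        img[xx > yy] = (30, 30, 200)
        labels = slic_segment(img, SlicParams(n_superpixels=2))
        assert self._boundary_recall(
            labels, lambda r, c: (c - r) / np.sqrt(2)
        ) >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        a = slic_segment(img, SlicParams(n_superpixels=8))
        b = slic_segment(img, SlicParams(n_superpixels=8))
        assert np.array_equal(a, b)


class TestConnectivity:
    def test_connected_map_unchanged_up_to_relabeling(self):
        labels = np.zeros((8, 8), np.int32)
        labels[:, 4:] = 1
        out = enforce_connectivity(labels, SlicParams(n_superpixels=2))
        assert np.array_equal(out, labels)

    def test_single_pixel_island_absorbed(self):
        labels = np.zeros((10, 10), np.int32)
        labels[5, 5] = 1
        out = enforce_connectivity(labels, SlicParams(n_superpixels=2))
        assert (out == out[0, 0]).all()

    def test_disconnected_label_split_then_merged_by_size(self):
        labels = np.zeros((6, 12), np.int32)
        labels[:, 8:] = 1
        labels[2:4, 2:4] = 1  # 4-pixel island sharing label 1, far from its bulk
        out = enforce_connectivity(labels, SlicParams(n_superpixels=2))
        # the island (4 px < 0.25 * 36) is merged into the surrounding region
        assert len(np.unique(out)) == 2
        assert len(np.unique(out[2:4, 2:4])) == 1
        assert out[2, 2] == out[0, 0]

    def test_large_disconnected_component_becomes_its_own_label(self):
        labels = np.zeros((6, 18), np.int32)
        labels[:, 12:] = 1
        labels[:, :6] = 1  # two big blocks share label 1
        out = enforce_connectivity(labels, SlicParams(n_superpixels=3))
        assert len(np.unique(out)) == 3


def test_superpixel_map_round_trips_through_png(tmp_path):
    from earcount.slic import load_superpixel_map, save_superpixel_map

    rng = np.random.default_rng(11)
    img = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
    params = SlicParams(n_superpixels=6)
    labels = slic_segment(img, params)
    save_superpixel_map(tmp_path / "map.png", tmp_path / "map.json", labels, params)
    loaded, meta = load_superpixel_map(tmp_path / "map.png", tmp_path / "map.json")
    assert np.array_equal(loaded, labels)
    assert meta["K"] == labels.max() + 1
    assert meta["params"]["n_superpixels"] == 6


class TestRegions:
    def test_single_region_covers_whole_image(self):
        img = uniform_image(6, 7)
        regions = extract_regions(img, np.zeros((6, 7), np.int32))
        assert len(regions) == 1
        r = regions[0]
        assert r.box == (0, 0, 7, 6)
        assert r.mask.all() and np.array_equal(r.crop, img)

    def test_quadrants_give_four_full_crops(self):
        img = uniform_image(10, 10)
        labels = np.zeros((10, 10), np.int32)
        labels[:5, 5:] = 1
        labels[5:, :5] = 2
        labels[5:, 5:] = 3
        regions = extract_regions(img, labels)
        assert len(regions) == 4
        for r in regions:
            assert r.crop.shape == (5, 5, 3) and r.mask.all()

    def test_irregular_region_mask_excludes_neighbors(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        labels = slic_segment(img, SlicParams(n_superpixels=4))
        regions = extract_regions(img, labels)
        cover = np.zeros((20, 20), int)
        for r in regions:
            x0, y0, x1, y1 = r.box
            # ownership mask agrees with a per-pixel label lookup
            assert np.array_equal(r.mask, labels[y0:y1, x0:x1] == r.label)
            cover[y0:y1, x0:x1] += r.mask
        assert (cover == 1).all()
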