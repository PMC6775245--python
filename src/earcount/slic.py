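"""SLIC superpixel partitioning.

Localized k-means in the 5-D (l, a, b, x, y) feature space: cluster centers are
seeded on a regular grid with spacing ``S = sqrt(H*W/N)``, perturbed to the
lowest-gradient pixel in a 3x3 neighborhood, then iteratively refined. Each
center only competes for pixels inside a 2S x 2S window around it, which makes
the algorithm linear in image size. The spectral-spatial distance is

    D = sqrt(d_lab^2 + (m/S)^2 * d_xy^2)

where the compactness ``m`` trades boundary adherence (small m) against square,
compact regions (large m). A final connectivity pass splits disconnected labels
and absorbs small islands into their neighbors so the output is a partition of
the image into 4-connected regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

from .imaging import as_rgb, to_cielab

__all__ = [
    "SlicParams",
    "RegionInput",
    "initialize_centers",
    "slic_segment",
    "enforce_connectivity",
    "extract_regions",
    "save_superpixel_map",
    "load_superpixel_map",
]


@dataclass
class SlicParams:
    """Parameters of the superpixel stage.

    ``n_superpixels`` defaults to 3000, chosen to avoid oversegmentation on
    multi-megapixel canopy images while keeping superpixels small enough to be
    color-homogeneous. ``compactness`` weighs spatial against color distance;
    ``min_region_fraction`` is the island-absorption threshold relative to the
    average superpixel area.
    """

    n_superpixels: int = 3000
    compactness: float = 10.0
    max_iterations: int = 10
    min_region_fraction: float = 0.25

    def validate(self, n_pixels: int | None = None) -> None:
        if self.n_superpixels < 1:
            raise ValueError("n_superpixels must be positive")
        if self.compactness <= 0:
            raise ValueError("compactness must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not 0 < self.min_region_fraction < 1:
            raise ValueError("min_region_fraction must lie in (0, 1)")
        if n_pixels is not None and self.n_superpixels > n_pixels:
            raise ValueError(
                f"n_superpixels={self.n_superpixels} exceeds pixel count {n_pixels}"
            )


@dataclass
class RegionInput:
    """One superpixel, cropped to its bounding box.

    ``crop`` is the RGB crop, ``mask`` the boolean ownership grid within the
    crop (pixels of the box owned by other superpixels are False), and ``box``
    the (x0, y0, x1, y1) half-open image coordinates of the crop.
    """

    crop: np.ndarray
    mask: np.ndarray
    box: tuple[int, int, int, int]
    label: int = field(default=-1)


def _lab_gradient(lab: np.ndarray) -> np.ndarray:
    """Squared CIELAB gradient magnitude via central differences (edge-clipped)."""
    pad = np.pad(lab, ((0, 0), (1, 1), (0, 0)), mode="edge")
    gx = pad[:, 2:] - pad[:, :-2]
    pad = np.pad(lab, ((1, 1), (0, 0), (0, 0)), mode="edge")
    gy = pad[2:] - pad[:-2]
    return (gx**2).sum(axis=2) + (gy**2).sum(axis=2)


def initialize_centers(lab: np.ndarray, params: SlicParams) -> np.ndarray:
    """Seed cluster centers on a regular grid, perturbed off gradients.

    Returns a ``(K, 5)`` float array of (l, a, b, x, y) centers. K is the size
    of an aspect-balanced nx-by-ny grid approximating ``n_superpixels`` (K can
    differ slightly from N when N does not tile the image). Each seed is
    snapped to the pixel of lowest color gradient in its 3x3 neighborhood so
    seeds do not start on an edge; ties keep the scan-order-first pixel.
    """
    H, W = lab.shape[:2]
    params.validate(H * W)
    N = params.n_superpixels
    # aspect-balanced grid whose cell count approximates N
    nx = max(1, int(np.ceil(np.sqrt(N * W / H))))
    ny = max(1, min(int(round(N / nx)), H))
    nx = min(nx, W)
    grad = _lab_gradient(lab)
    centers = []
    for gy in range(ny):
        cy = (gy + 0.5) * H / ny
        for gx in range(nx):
            cx = (gx + 0.5) * W / nx
            px = min(W - 1, int(cx))
            py = min(H - 1, int(cy))
            # perturb to the lowest-gradient pixel in the 3x3 neighborhood
            best = (py, px)
            best_g = grad[py, px]
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    qy, qx = py + dy, px + dx
                    if 0 <= qy < H and 0 <= qx < W and grad[qy, qx] < best_g:
                        best_g = grad[qy, qx]
                        best = (qy, qx)
            by, bx = best
            l, a, b = lab[by, bx]
            centers.append((l, a, b, float(bx), float(by)))
    return np.asarray(centers, dtype=np.float64)


def _assign(lab, centers, S, inv_S2m2, yy, xx):
    """One localized assignment sweep; returns the label grid.

    Each center claims pixels inside its 2S x 2S window when its squared 5-D
    distance beats the incumbent; strict inequality means that on exact ties
    the lowest center index wins.
    """
    H, W = lab.shape[:2]
    best = np.full((H, W), np.inf)
    labels = np.full((H, W), -1, dtype=np.int32)
    for k, (cl, ca, cb, cx, cy) in enumerate(centers):
        x0 = max(0, int(np.floor(cx - S)))
        x1 = min(W, int(np.ceil(cx + S)) + 1)
        y0 = max(0, int(np.floor(cy - S)))
        y1 = min(H, int(np.ceil(cy + S)) + 1)
        win = lab[y0:y1, x0:x1]
        d_lab = (win[..., 0] - cl) ** 2 + (win[..., 1] - ca) ** 2 + (win[..., 2] - cb) ** 2
        d_xy = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
        D = d_lab + inv_S2m2 * d_xy
        sub_best = best[y0:y1, x0:x1]
        upd = D < sub_best
        sub_best[upd] = D[upd]
        labels[y0:y1, x0:x1][upd] = k
    return labels


def slic_segment(
    img: np.ndarray,
    params: SlicParams | None = None,
    *,
    enforce: bool = True,
) -> np.ndarray:
    """Partition an RGB image into superpixels; returns an (H, W) int32 label map.

    Runs ``max_iterations`` rounds of localized assignment followed by a
    k-means center update (empty clusters keep their previous center); the
    returned map comes from the final assignment sweep. With ``enforce`` (the
    default) disconnected labels are split and small islands merged, so every
    returned label is a 4-connected region and labels are renumbered 0..K-1 in
    row-major order of first occurrence.
    """
    rgb = as_rgb(img)
    if params is None:
        params = SlicParams()
    H, W = rgb.shape[:2]
    params.validate(H * W)
    lab = to_cielab(rgb)
    S = np.sqrt(H * W / params.n_superpixels)
    inv_S2m2 = (params.compactness / S) ** 2
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    centers = initialize_centers(lab, params)
    # on tiny images the 2S x 2S window cannot be guaranteed to reach every
    # pixel from an off-center seed; fall back to a global search there
    search = S if 2 * S < max(H, W) else float(max(H, W))
    labels = None
    feats = (lab[..., 0].ravel(), lab[..., 1].ravel(), lab[..., 2].ravel(),
             xx.ravel(), yy.ravel())
    for _ in range(params.max_iterations):
        labels = _assign(lab, centers, search, inv_S2m2, yy, xx)
        # k-means update: move each center to the mean of its pixels in 5-D
        # (pixels out of every search window stay unassigned this round)
        flat = labels.ravel()
        valid = flat >= 0
        fv = flat[valid]
        counts = np.bincount(fv, minlength=len(centers)).astype(np.float64)
        nonempty = counts > 0
        for d in range(5):
            sums = np.bincount(fv, weights=feats[d][valid], minlength=len(centers))
            centers[nonempty, d] = sums[nonempty] / counts[nonempty]
    # Window clipping guarantees coverage for sane N, but guard regardless:
    if (labels == -1).any():
        missing = labels == -1
        full = (
            (lab[..., 0][..., None] - centers[:, 0]) ** 2
            + (lab[..., 1][..., None] - centers[:, 1]) ** 2
            + (lab[..., 2][..., None] - centers[:, 2]) ** 2
            + inv_S2m2
            * ((xx[..., None] - centers[:, 3]) ** 2 + (yy[..., None] - centers[:, 4]) ** 2)
        )
        labels[missing] = np.argmin(full, axis=-1)[missing].astype(np.int32)
    if enforce:
        labels = enforce_connectivity(labels, params)
    return labels


def enforce_connectivity(labels: np.ndarray, params: SlicParams) -> np.ndarray:
    """Split disconnected labels and absorb small islands.

    Every 4-connected component becomes its own region; components smaller
    than ``min_region_fraction * (H*W / n_superpixels)`` are merged into the
    adjacent component sharing the longest boundary (lowest id on ties) until
    none remain (or a single region is left). Output labels are renumbered
    0..K-1 in row-major order of first occurrence.
    """
    labels = np.asarray(labels)
    H, W = labels.shape
    min_size = params.min_region_fraction * (H * W / params.n_superpixels)
    comp = measure.label(labels, connectivity=1)  # components of equal value, 1-based
    while True:
        ids, sizes = np.unique(comp, return_counts=True)
        if len(ids) == 1:
            break
        small = ids[sizes < min_size]
        if len(small) == 0:
            break
        # merge the smallest offender first
        target = small[np.argsort(sizes[np.isin(ids, small)])[0]]
        sel = comp == target
        # 4-connected neighbors across the component boundary
        grown = ndi.binary_dilation(sel, structure=ndi.generate_binary_structure(2, 1))
        border = grown & ~sel
        vals, counts = np.unique(comp[border], return_counts=True)
        if len(vals) == 0:
            break
        merge_into = vals[np.argmax(counts)]
        comp[sel] = merge_into
    # renumber row-major by first occurrence
    flat = comp.ravel()
    _, first_idx, inverse = np.unique(flat, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_idx))
    return order[inverse].reshape(H, W).astype(np.int32)


def extract_regions(img: np.ndarray, labels: np.ndarray) -> list[RegionInput]:
    """Cut each superpixel out of the image as a (crop, ownership-mask, box) triple.

    The union of the ownership masks covers the image exactly once, so
    predictions made per region can be stitched back without overlap.
    """
    rgb = as_rgb(img)
    labels = np.asarray(labels)
    if labels.shape != rgb.shape[:2]:
        raise ValueError("label map shape does not match image")
    regions: list[RegionInput] = []
    slices = ndi.find_objects(labels + 1)
    for k, sl in enumerate(slices):
        if sl is None:
            continue
        ys, xs = sl
        crop = rgb[ys, xs]
        mask = labels[ys, xs] == k
        box = (xs.start, ys.start, xs.stop, ys.stop)
        regions.append(RegionInput(crop=crop, mask=mask, box=box, label=k))
    return regions


def save_superpixel_map(path_png, path_meta, labels: np.ndarray, params: SlicParams) -> None:
    """Write a label map as a 16-bit PNG plus a JSON sidecar (K and parameters)."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    iio.imwrite(path_png, labels.astype(np.uint16))
    meta = {"K": int(labels.max()) + 1, "params": asdict(params)}
    with open(path_meta, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_superpixel_map(path_png, path_meta=None):
    """Read a label map written by :func:`save_superpixel_map`."""
    import imageio.v3 as iio

    labels = iio.imread(path_png).astype(np.int32)
    meta = None
    if path_meta is not None:
        with open(path_meta) as fh:
            meta = json.load(fh)
    return labels, meta
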