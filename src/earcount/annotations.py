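"""Training-patch construction from polygon/box annotations.

Ears are annotated as polygons traced around each spike; background examples
(leaves, stems, soil) as rectangular boxes. Both come from VIA (VGG Image
Annotator) JSON exports. An ear patch is the polygon's bounding-box crop with
the rasterized polygon interior as its pixel mask; a background patch is the
box crop with an all-zero mask. Augmentation simulates field illumination and
pose variation: HSV shifts, brightness, gamma encoding, flips, rotation, and
zoom, each applied independently with a configured probability; geometric
transforms are applied identically to image and mask.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from .imaging import apply_gamma, as_rgb

__all__ = [
    "AnnotatedShape",
    "Patch",
    "PatchSet",
    "AugmentParams",
    "read_via_annotations",
    "build_patches",
    "augment",
    "split_train_val",
    "save_patchset",
    "load_patchset",
]

logger = logging.getLogger(__name__)

EAR = "ear"
BACKGROUND = "background"


@dataclass
class AnnotatedShape:
    image_id: str
    kind: str  # "polygon" | "box"
    vertices: list[tuple[float, float]]  # (x, y) pixel coordinates
    class_label: str  # "ear" | "background"

    def __post_init__(self):
        if self.kind not in ("polygon", "box"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "polygon" and len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if self.kind == "box" and len(self.vertices) != 2:
            raise ValueError("box needs exactly 2 corner points")
        if self.class_label not in (EAR, BACKGROUND):
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass
class Patch:
    """A labeled (image, mask) training pair. Mask is 1 on ear pixels.

    ``origin`` optionally records where the crop came from, as
    ``(source_id, y0, x0, y1, x1)`` in source-image coordinates."""

    image: np.ndarray
    mask: np.ndarray
    class_label: str
    origin: tuple | None = None

    def __post_init__(self):
        self.image = as_rgb(self.image)
        self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must equal image shape")
        if self.class_label == BACKGROUND and self.mask.any():
            raise ValueError("background patch must have an all-zero mask")
        if self.class_label == EAR and not self.mask.any():
            raise ValueError("ear patch must have at least one positive pixel")


@dataclass
class PatchSet:
    patches: list[Patch]

    def __post_init__(self):
        if not self.patches:
            raise ValueError("PatchSet must be nonempty")

    def __len__(self):
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, i):
        return self.patches[i]

    @property
    def class_counts(self) -> dict:
        counts = {EAR: 0, BACKGROUND: 0}
        for p in self.patches:
            counts[p.class_label] += 1
        return counts


@dataclass
class AugmentParams:
    """Augmentation magnitudes. Every transform fires independently with
    ``apply_probability``; zero-width ranges make a transform a no-op."""

    apply_probability: float = 0.5
    rotation_range: float = 30.0  # degrees, symmetric
    zoom_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    hue_shift: float = 10.0  # degrees
    saturation_range: tuple[float, float] = (0.8, 1.2)
    value_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.5, 2.0)
    flip_horizontal: bool = True
    flip_vertical: bool = True

    def __post_init__(self):
        if not 0 <= self.apply_probability <= 1:
            raise ValueError("apply_probability must lie in [0, 1]")
        for name in ("zoom_range", "brightness_range", "saturation_range",
                     "value_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")


# ---------------------------------------------------------------------------
# VIA JSON

def _via_regions(path):
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "_via_img_metadata" in data:
        data = data["_via_img_metadata"]
    if isinstance(data, dict):
        entries = list(data.values())
    elif isinstance(data, list):
        entries = data
    else:
        raise ValueError("unrecognized VIA JSON layout")
    for entry in entries:
        if not isinstance(entry, dict) or "filename" not in entry:
            raise ValueError(f"malformed VIA record (no filename): {entry!r:.200}")
        yield entry["filename"], entry.get("regions", [])


def read_via_annotations(path, class_attribute: str = "class") -> list[AnnotatedShape]:
    """Parse a VIA project/export JSON into a flat list of annotated shapes.

    Both the ``_via_img_metadata`` dict dialect and the plain list export are
    accepted. The class of each region is read from ``class_attribute`` in its
    region attributes; regions with an unknown or missing class are skipped
    with a logged warning, malformed shape records raise ``ValueError``.
    """
    shapes: list[AnnotatedShape] = []
    for filename, regions in _via_regions(path):
        for i, region in enumerate(regions):
            where = f"image {filename!r} region {i}"
            try:
                sa = region["shape_attributes"]
                name = sa["name"]
            except (KeyError, TypeError) as exc:
                raise ValueError(f"malformed VIA record at {where}: {exc}") from exc
            label = region.get("region_attributes", {}).get(class_attribute)
            if label not in (EAR, BACKGROUND):
                logger.warning("skipping %s: unknown class %r", where, label)
                continue
            if name in ("polygon", "polyline"):
                try:
                    xs = sa["all_points_x"]
                    ys = sa["all_points_y"]
                except KeyError as exc:
                    raise ValueError(f"malformed polygon at {where}") from exc
                verts = list(zip(map(float, xs), map(float, ys)))
                shapes.append(AnnotatedShape(filename, "polygon", verts, label))
            elif name == "rect":
                try:
                    x, y, w, h = sa["x"], sa["y"], sa["width"], sa["height"]
                except KeyError as exc:
                    raise ValueError(f"malformed rect at {where}") from exc
                verts = [(float(x), float(y)), (float(x + w), float(y + h))]
                shapes.append(AnnotatedShape(filename, "box", verts, label))
            else:
                logger.warning("skipping %s: unsupported shape %r", where, name)
    return shapes


# ---------------------------------------------------------------------------
# Patch construction

def build_patches(
    images: dict,
    shapes: list[AnnotatedShape],
    margin: float = 0.1,
) -> PatchSet:
    """Cut labeled patches out of full images.

    ``images`` maps image ids to RGB arrays. Ear polygons become bounding-box
    crops (expanded by ``margin`` of the box size) with the polygon interior
    rasterized as the mask; background boxes become crops with zero masks.
    Shapes reaching outside the image are clipped with a warning; degenerate
    (zero-area) shapes are skipped.
    """
    patches: list[Patch] = []
    for shape in shapes:
        if shape.image_id not in images:
            raise KeyError(f"shape references unknown image {shape.image_id!r}")
        img = as_rgb(images[shape.image_id])
        H, W = img.shape[:2]
        verts = np.asarray(shape.vertices, dtype=float)
        if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
                or verts[:, 0].max() > W or verts[:, 1].max() > H):
            warnings.warn(f"shape on {shape.image_id!r} reaches outside the image; clipping")
            verts[:, 0] = verts[:, 0].clip(0, W)
            verts[:, 1] = verts[:, 1].clip(0, H)
        x0, y0 = verts.min(axis=0)
        x1, y1 = verts.max(axis=0)
        if shape.kind == "polygon":
            mx = margin * (x1 - x0)
            my = margin * (y1 - y0)
            x0, x1 = x0 - mx, x1 + mx
            y0, y1 = y0 - my, y1 + my
        ix0, iy0 = max(0, int(np.floor(x0))), max(0, int(np.floor(y0)))
        ix1, iy1 = min(W, int(np.ceil(x1))), min(H, int(np.ceil(y1)))
        if ix1 - ix0 < 1 or iy1 - iy0 < 1:
            logger.warning("skipping degenerate shape on %r", shape.image_id)
            continue
        crop = img[iy0:iy1, ix0:ix1]
        if shape.class_label == BACKGROUND:
            patches.append(Patch(crop, np.zeros(crop.shape[:2], np.uint8), BACKGROUND))
            continue
        rr, cc = skdraw.polygon(verts[:, 1] - iy0, verts[:, 0] - ix0, crop.shape[:2])
        mask = np.zeros(crop.shape[:2], np.uint8)
        mask[rr, cc] = 1
        if not mask.any():
            logger.warning("skipping zero-area polygon on %r", shape.image_id)
            continue
        patches.append(Patch(crop, mask, EAR))
    return PatchSet(patches)


# ---------------------------------------------------------------------------
# Augmentation

def _zoom(img, mask, factor):
    """Zoom about the center, keeping the original patch size."""
    H, W = mask.shape
    zi = sktransform.rescale(img.astype(float), factor, channel_axis=2, order=1,
                             mode="edge", anti_aliasing=False)
    zm = sktransform.rescale(mask.astype(float), factor, order=0,
                             mode="constant", cval=0, anti_aliasing=False)
    h, w = zm.shape

    def fit(arr, fill):
        if h >= H:
            t = (h - H) // 2
            arr = arr[t:t + H]
        if w >= W:
            l = (w - W) // 2
            arr = arr[:, l:l + W]
        ph, pw = H - arr.shape[0], W - arr.shape[1]
        if ph > 0 or pw > 0:
            pads = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
            if arr.ndim == 3:
                pads.append((0, 0))
            arr = np.pad(arr, pads, mode="edge" if fill == "edge" else "constant")
        return arr

    return fit(zi, "edge"), fit(zm, "zero")


def augment(patch: Patch, params: AugmentParams, rng: np.random.Generator) -> Patch:
    """Randomly transformed copy of a patch.

    Geometric transforms (flips, rotation, zoom) move image and mask together,
    with nearest-neighbor resampling for the mask; photometric transforms (HSV
    shift, brightness, gamma) touch the image only. A geometric draw that
    would wipe out an ear mask entirely is skipped, so the patch class is
    preserved.
    """
    img = patch.image.astype(float)
    mask = patch.mask.astype(float)
    p = params.apply_probability

    if params.flip_horizontal and rng.random() < p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if params.flip_vertical and rng.random() < p:
        img, mask = img[::-1], mask[::-1]
    if params.rotation_range > 0 and rng.random() < p:
        angle = rng.uniform(-params.rotation_range, params.rotation_range)
        ri = sktransform.rotate(img, angle, mode="edge", order=1, preserve_range=True)
        rm = sktransform.rotate(mask, angle, mode="constant", cval=0, order=0,
                                preserve_range=True)
        if rm.any() or not mask.any():
            img, mask = ri, rm
    if params.zoom_range != (1.0, 1.0) and rng.random() < p:
        factor = rng.uniform(*params.zoom_range)
        zi, zm = _zoom(img, mask, factor)
        if zm.any() or not mask.any():
            img, mask = zi, zm

    hsv_active = (params.hue_shift != 0 or params.saturation_range != (1.0, 1.0)
                  or params.value_range != (1.0, 1.0))
    if hsv_active and rng.random() < p:  # HSV jitter
        hsv = rgb2hsv(np.clip(img, 0, 255).astype(np.uint8))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-params.hue_shift, params.hue_shift) / 360.0) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*params.saturation_range), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(*params.value_range), 0, 1)
        img = hsv2rgb(hsv) * 255.0
    if params.brightness_range != (1.0, 1.0) and rng.random() < p:
        img = img * rng.uniform(*params.brightness_range)
    if params.gamma_range != (1.0, 1.0) and rng.random() < p:
        gamma = rng.uniform(*params.gamma_range)
        img = apply_gamma(np.clip(img, 0, 255).astype(np.uint8), gamma).astype(float)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Patch(img, mask > 0.5, patch.class_label)


def save_patchset(directory, patchset: PatchSet) -> None:
    """Cache a PatchSet as paired image/mask PNGs plus a CSV manifest."""
    import csv
    from pathlib import Path

    from .imaging import write_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "class", "image", "mask"])
        for i, patch in enumerate(patchset):
            img_name = f"patch_{i:05d}.png"
            mask_name = f"patch_{i:05d}_mask.png"
            write_image(directory / img_name, patch.image)
            write_image(directory / mask_name, patch.mask * 255)
            writer.writerow([i, patch.class_label, img_name, mask_name])


def load_patchset(directory) -> PatchSet:
    """Read a PatchSet written by :func:`save_patchset`."""
    import csv
    from pathlib import Path

    from .imaging import read_image

    directory = Path(directory)
    patches = []
    with open(directory / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = read_image(directory / row["image"])
            mask = read_image(directory / row["mask"])[..., 0] > 127
            patches.append(Patch(img, mask.astype(np.uint8), row["class"]))
    return PatchSet(patches)


def split_train_val(
    patchset: PatchSet, val_fraction: float = 0.2, seed: int = 0
) -> tuple[PatchSet, PatchSet]:
    """Seeded random split into (train, validation); validation gets
    ``round(val_fraction * n)`` patches, the remainder trains."""
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    n = len(patchset)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    idx = np.random.default_rng(seed).permutation(n)
    val = [patchset[i] for i in idx[:n_val]]
    train = [patchset[i] for i in idx[n_val:]]
    return PatchSet(train), PatchSet(val)
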