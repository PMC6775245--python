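"""From probability map to ear count and ear density.

The stitched probability map is thresholded, denoised with a 7x7 median
filter, and touching ears are separated by marker-based watershed: markers are
the regional maxima of the Euclidean distance transform (with a minimum peak
separation derived from the typical ear size), and flooding runs on the
negated distance transform inside the foreground. Components below a minimum
area are discarded; each surviving component contributes one closed contour
and one count.

Ear density uses an in-image ground standard: a sheet of known physical area
(an A4 page by default) whose pixel area fixes the m^2-per-pixel^2 scale, so

    ears/m^2 = count / (H * W * physical_area / pixel_area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .imaging import as_rgb, median_filter

__all__ = [
    "CountResult",
    "GroundStandard",
    "GroundStandardNotFound",
    "binarize",
    "count_ears",
    "ears_per_m2",
    "detect_ground_standard",
    "render_overlay",
]

A4_AREA_M2 = 0.210 * 0.297  # 0.06237


class GroundStandardNotFound(RuntimeError):
    """No plausible ground-standard sheet found in the image."""


@dataclass
class GroundStandard:
    """A quadrilateral of known physical area placed in the scene."""

    corners: np.ndarray  # (4, 2) float, (x, y) pixel coordinates
    physical_area: float = A4_AREA_M2  # m^2

    def __post_init__(self):
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        if self.physical_area <= 0:
            raise ValueError("physical_area must be positive")

    @property
    def pixel_area(self) -> float:
        x, y = self.corners[:, 0], self.corners[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


@dataclass
class CountResult:
    mask: np.ndarray  # final binary mask after denoising/area filtering
    contours: list[np.ndarray]  # each (n, 2) of (row, col) boundary points
    count: int
    labels: np.ndarray | None = None  # instance labels from the watershed
    ears_per_m2: float | None = None

    def __post_init__(self):
        if self.count != len(self.contours):
            raise ValueError("count must equal the number of contours")


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; pixels >= threshold become foreground."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    pm = np.asarray(prob_map, dtype=float)
    return (pm >= threshold).astype(np.uint8)


def _component_contour(component: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a single binary component."""
    padded = np.pad(component.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    longest = max(contours, key=len)
    return longest - 1.0  # undo the pad offset


def count_ears(
    mask: np.ndarray,
    min_area: int | None = None,
    min_peak_separation: int | None = None,
    median_window: int = 7,
) -> CountResult:
    """Count individual ears in a binary mask.

    ``min_peak_separation`` defaults to 0.8x the median inscribed radius of
    the foreground components, so split markers cannot sit closer than about
    one ear half-width; ``min_area`` defaults to 0.02% of the image pixels.
    An empty mask yields count 0.
    """
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    H, W = mask.shape
    if min_area is None:
        min_area = max(1, int(round(2e-4 * H * W)))
    clean = median_filter(mask, median_window) if median_window else mask
    if not clean.any():
        return CountResult(mask=clean, contours=[], count=0,
                           labels=np.zeros_like(clean, dtype=np.int32))
    comp, n_comp = ndi.label(clean)
    edt = ndi.distance_transform_edt(clean)
    if min_peak_separation is None:
        # typical ear half-width from the distance transform: the per-component
        # EDT maximum is the inscribed radius, which (unlike an area-based
        # diameter) is not inflated when two ears merge into one component
        radii = ndi.maximum(edt, comp, index=np.arange(1, n_comp + 1))
        min_peak_separation = max(1, int(round(0.8 * float(np.median(radii)))))
    # smooth the ridge so pixelation bumps along an elongated ear do not
    # spawn spurious markers; flooding still runs on the exact transform
    smooth = ndi.gaussian_filter(edt, sigma=1.0)
    peaks = peak_local_max(
        smooth, min_distance=int(min_peak_separation), labels=comp, exclude_border=False
    )
    markers = np.zeros_like(clean, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # guarantee at least one marker per component
    next_id = len(peaks) + 1
    marked = set(np.unique(comp[markers > 0]))
    for k in range(1, n_comp + 1):
        if k not in marked:
            sel = comp == k
            flat = np.argmax(np.where(sel, edt, -1))
            markers.flat[flat] = next_id
            next_id += 1
    ws = watershed(-edt, markers, mask=clean.astype(bool))
    # discard small fragments, relabel densely
    out = np.zeros_like(ws, dtype=np.int32)
    contours = []
    nid = 0
    for k in np.unique(ws[ws > 0]):
        sel = ws == k
        if int(sel.sum()) < min_area:
            continue
        nid += 1
        out[sel] = nid
        contours.append(_component_contour(sel))
    return CountResult(mask=(out > 0).astype(np.uint8), contours=contours,
                       count=nid, labels=out)


def ears_per_m2(count: int, standard: GroundStandard, image_shape) -> float:
    """Convert an image-total ear count into ears per square meter.

    The standard's pixel area P and physical area give the ground scale
    (m^2 per pixel^2); the imaged area is H*W times that scale.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    P = standard.pixel_area
    if P <= 0:
        raise ValueError("degenerate ground standard (zero pixel area)")
    H, W = image_shape[:2]
    scale2 = standard.physical_area / P
    imaged_area = H * W * scale2
    return float(count / imaged_area)


def detect_ground_standard(
    img: np.ndarray,
    physical_area: float = A4_AREA_M2,
    min_value: float = 0.5,
    max_saturation: float = 0.15,
    min_area_fraction: float = 0.002,
    min_rectangularity: float = 0.80,
) -> GroundStandard:
    """Find a bright, low-saturation quadrilateral (the reference sheet).

    The largest connected region passing the brightness/saturation gate (a
    white sheet keeps near-zero saturation even in shade, unlike vegetation)
    is fitted with the minimum-area rotated rectangle of its boundary pixel
    centers; the tight saturation gate excludes the blurred half-sheet halo,
    so pixel centers track the physical edge. The candidate is rejected
    unless it is large enough and fills >= ``min_rectangularity`` of the
    rectangle. Raises :class:`GroundStandardNotFound` otherwise — corners can
    always be supplied manually instead.
    """
    from shapely.geometry import MultiPoint

    rgb = as_rgb(img)
    H, W = rgb.shape[:2]
    hsv = rgb2hsv(rgb)
    cand = (hsv[..., 2] >= min_value) & (hsv[..., 1] <= max_saturation)
    comp, n_comp = ndi.label(cand)
    if n_comp == 0:
        raise GroundStandardNotFound(
            "no bright low-saturation region found; supply the four corners manually"
        )
    areas = ndi.sum_labels(cand, comp, index=np.arange(1, n_comp + 1))
    order = np.argsort(areas)[::-1]
    for k in order[:3]:
        area = float(areas[k])
        if area < min_area_fraction * H * W:
            break
        sel = comp == (k + 1)
        boundary = sel & ~ndi.binary_erosion(sel)
        rr, cc = np.nonzero(boundary)
        rect = MultiPoint(
            [(float(c), float(r)) for r, c in zip(rr, cc)]
        ).minimum_rotated_rectangle
        rect_area = rect.area
        if rect_area <= 0 or area / rect_area < min_rectangularity:
            continue
        corners = np.asarray(list(rect.exterior.coords)[:4], dtype=float)
        return GroundStandard(corners=corners, physical_area=physical_area)
    raise GroundStandardNotFound(
        "no candidate passed the area/rectangularity checks; "
        "supply the four corners manually"
    )


def render_overlay(img: np.ndarray, result: CountResult) -> np.ndarray:
    """Numbered contour overlay on a copy of the input (input left untouched)."""
    from PIL import Image, ImageDraw

    rgb = as_rgb(img)
    if result.count == 0:
        return rgb.copy()
    pil = Image.fromarray(rgb.copy())
    drw = ImageDraw.Draw(pil)
    for i, contour in enumerate(result.contours, start=1):
        xy = [(float(c), float(r)) for r, c in contour]
        drw.line(xy + xy[:1], fill=(255, 40, 40), width=1)
        cy, cx = contour.mean(axis=0)
        drw.text((float(cx), float(cy)), str(i), fill=(255, 255, 0))
    return np.asarray(pil)
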