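"""Synthetic overhead canopy scenes with exact ground truth.

Emulates nadir photographs of a wheat canopy at desk scale: a low-frequency
green/brown background texture, golden elliptical spikes with spikelet-like
intensity banding and optional awn strokes, an illumination gradient, soft
shadows, Gaussian blur, and an optional white A4-like ground-standard sheet.
Every scene carries its exact pre-blur instance labels and ear mask, so the
true count is known by construction.

The generator is fully seeded: the same ``SceneParams`` (including seed)
reproduce a byte-identical scene. Masks are captured before blur and
photometric effects, an idealization that keeps ground truth crisp.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import draw as skdraw

from .annotations import BACKGROUND, EAR, Patch, PatchSet

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "generate_patchset"]

# mean RGB of the procedural palette; per-scene jitter is applied around these
GREEN = np.array([72.0, 112.0, 52.0])
BROWN = np.array([104.0, 88.0, 66.0])
GOLD = np.array([196.0, 166.0, 68.0])
AWN = np.array([205.0, 190.0, 135.0])
SHEET = 238.0


@dataclass
class SceneParams:
    """Study conditions of a synthetic scene.

    Defaults describe a moderately dense desk-scale canopy: 24 ears of
    16-26 px major semi-axis on a 320 px square image, at most 20% pairwise
    instance overlap, half the ears awned, gentle illumination gradient and
    1 px blur. Ear size is set several times the 7 px median-filter window
    used downstream, matching the relative scale of ears in real canopy
    photographs.
    """

    height: int = 320
    width: int = 320
    n_ears: int = 24
    major_axis: tuple[float, float] = (16.0, 26.0)  # semi-axis, px
    minor_axis: tuple[float, float] = (6.0, 10.0)
    # max pairwise |A∩B| / min(|A|,|B|); 0.07 matches an overlap depth of
    # roughly 30% of the ear half-width, the regime watershed can still split
    overlap_limit: float = 0.07
    min_clearance: float = 0.0  # px of empty space required around each new ear
    awn_probability: float = 0.5
    awn_strokes: int = 5
    background_scale: int = 24  # px wavelength of the background texture
    illumination_amplitude: float = 0.2
    n_shadows: int = 3
    shadow_depth: float = 0.2
    blur_sigma: float = 1.0
    include_standard: bool = False
    standard_size: tuple[float, float] = (62.0, 88.0)  # px, A4 aspect 210:297
    standard_center: tuple[float, float] | None = None  # (x, y); None = random
    seed: int = 0

    def validate(self):
        if self.height < 1 or self.width < 1 or self.n_ears < 0:
            raise ValueError("sizes must be positive, n_ears nonnegative")
        if not 0 <= self.overlap_limit < 1:
            raise ValueError("overlap_limit must lie in [0, 1)")
        for lo, hi in (self.major_axis, self.minor_axis):
            if lo <= 0 or hi < lo:
                raise ValueError("axis ranges must be positive and ordered")


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    ear_mask: np.ndarray  # (H, W) uint8 {0,1}
    instance_labels: np.ndarray  # (H, W) int32, 0 = background
    true_count: int
    standard_corners: np.ndarray | None  # (4, 2) float (x, y), or None
    params: SceneParams

    @property
    def standard_pixel_area(self) -> float | None:
        if self.standard_corners is None:
            return None
        x, y = self.standard_corners[:, 0], self.standard_corners[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def _texture(rng, H, W, scale):
    """Low-frequency field in [0, 1]: coarse noise grid upsampled and smoothed."""
    gh, gw = max(2, H // scale), max(2, W // scale)
    coarse = rng.random((gh, gw))
    fine = ndi.zoom(coarse, (H / gh, W / gw), order=3)[:H, :W]
    fine = fine - fine.min()
    rng_span = fine.max()
    return fine / rng_span if rng_span > 0 else fine


def _ellipse_pixels(cy, cx, a, b, angle, shape):
    rr, cc = skdraw.ellipse(cy, cx, b, a, shape=shape, rotation=angle)
    return rr, cc


def _paint_ear(img, rng, rr, cc, cy, cx, angle, a):
    """Golden spike with intensity banding along the major axis."""
    base = GOLD + rng.normal(0, 12, 3)
    # coordinate along the major axis for each pixel
    t = (cc - cx) * np.cos(angle) - (rr - cy) * np.sin(angle)
    period = rng.uniform(3.5, 6.0)
    band = 1.0 + 0.20 * np.sin(2 * np.pi * t / period)
    shade = 1.0 + rng.normal(0, 0.05, len(rr))
    img[rr, cc] = np.clip(base[None, :] * (band * shade)[:, None], 0, 255)


def _draw_awns(img, rng, cy, cx, a, angle, n_strokes, shape):
    """Thin pale strokes fanning out from one tip of the ellipse."""
    tip_y = cy - a * np.sin(angle)
    tip_x = cx + a * np.cos(angle)
    for _ in range(n_strokes):
        theta = angle + rng.normal(0, 0.35)
        length = rng.uniform(0.4, 0.9) * a
        ey = tip_y - length * np.sin(theta)
        ex = tip_x + length * np.cos(theta)
        rr, cc = skdraw.line(int(round(tip_y)), int(round(tip_x)),
                             int(round(ey)), int(round(ex)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        color = np.clip(AWN + rng.normal(0, 10, 3), 0, 255)
        # awns are sub-pixel thin: blend half-strength over the background
        img[rr[keep], cc[keep]] = 0.5 * img[rr[keep], cc[keep]] + 0.5 * color


def _standard_corners(params: SceneParams, rng) -> np.ndarray:
    H, W = params.height, params.width
    sw, sh = params.standard_size
    if params.standard_center is None:
        cx = rng.uniform(sw, W - sw)
        cy = rng.uniform(sh, H - sh)
    else:
        cx, cy = params.standard_center
    ang = rng.uniform(-0.2, 0.2)
    dx, dy = sw / 2, sh / 2
    rect = np.array([[-dx, -dy], [dx, -dy], [dx, dy], [-dx, dy]])
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return rect @ rot.T + np.array([cx, cy])


def generate_scene(params: SceneParams | None = None, **overrides) -> SyntheticScene:
    """Render one scene. Raises ``RuntimeError`` if ``n_ears`` instances cannot
    be placed within the overlap limit after bounded retries (400 per ear)."""
    if params is None:
        params = SceneParams(**overrides)
    elif overrides:
        params = SceneParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width

    # background: green/brown mottle plus fine grain
    mix = _texture(rng, H, W, params.background_scale)
    img = GREEN[None, None, :] * (1 - mix[..., None]) + BROWN[None, None, :] * mix[..., None]
    img = img + rng.normal(0, 6, (H, W, 3))

    corners = None
    sheet_mask = np.zeros((H, W), bool)
    if params.include_standard:
        corners = _standard_corners(params, rng)
        rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0], shape=(H, W))
        sheet_mask[rr, cc] = True

    instance_labels = np.zeros((H, W), np.int32)
    areas: list[int] = []
    instance_px: list[tuple[np.ndarray, np.ndarray]] = []
    placed = 0
    for i in range(params.n_ears):
        ok = False
        for _ in range(400):
            a = rng.uniform(*params.major_axis)
            b = rng.uniform(*params.minor_axis)
            angle = rng.uniform(0, np.pi)
            cy = rng.uniform(a, H - a)
            cx = rng.uniform(a, W - a)
            rr, cc = _ellipse_pixels(cy, cx, a, b, angle, (H, W))
            if len(rr) == 0 or sheet_mask[rr, cc].any():
                continue
            if params.min_clearance > 0 and placed > 0:
                if free_dist[rr, cc].min() <= params.min_clearance:
                    continue
            area = len(rr)
            hit = instance_labels[rr, cc]
            overlap_ok = True
            for j in np.unique(hit[hit > 0]):
                inter = int((hit == j).sum())
                if inter / min(area, areas[j - 1]) > params.overlap_limit:
                    overlap_ok = False
                    break
            if not overlap_ok:
                continue
            _paint_ear(img, rng, rr, cc, cy, cx, angle, a)
            if rng.random() < params.awn_probability:
                _draw_awns(img, rng, cy, cx, a, angle, params.awn_strokes, (H, W))
            instance_labels[rr, cc] = i + 1
            areas.append(area)
            instance_px.append((rr, cc))
            placed += 1
            if params.min_clearance > 0:
                free_dist = ndi.distance_transform_edt(instance_labels == 0)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place ear {i + 1}/{params.n_ears} within the overlap "
                "limit; reduce n_ears or raise overlap_limit"
            )

    if params.include_standard:
        img[sheet_mask] = SHEET + rng.normal(0, 3, (int(sheet_mask.sum()), 3))

    # photometrics applied after ground-truth capture
    ear_mask = (instance_labels > 0).astype(np.uint8)
    if params.illumination_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:H, 0:W]
        ramp = (xx * np.cos(theta) + yy * np.sin(theta)).astype(float)
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-9) - 0.5
        img = img * (1.0 + 2 * params.illumination_amplitude * ramp)[..., None]
    for _ in range(params.n_shadows):
        sy, sx = rng.uniform(0, H), rng.uniform(0, W)
        srad = rng.uniform(0.15, 0.3) * min(H, W)
        yy, xx = np.mgrid[0:H, 0:W]
        blob = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * srad**2)))
        img = img * (1.0 - params.shadow_depth * blob)[..., None]
    if params.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=(params.blur_sigma, params.blur_sigma, 0))

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=img,
        ear_mask=ear_mask,
        instance_labels=instance_labels,
        true_count=placed,
        standard_corners=corners,
        params=params,
    )


def generate_patchset(
    params: SceneParams | None = None,
    n_per_class: int = 100,
    seed: int = 0,
    margin: float = 0.2,
) -> PatchSet:
    """Balanced labeled patches cut from freshly generated scenes.

    Ear patches are instance bounding boxes (expanded by ``margin``) with the
    scene's exact ear mask inside the box; background patches are ear-free
    crops with all-zero masks. Scenes are generated (seeded from ``seed``)
    until both classes reach ``n_per_class``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)
    ears: list[Patch] = []
    bgs: list[Patch] = []
    scene_i = 0
    while len(ears) < n_per_class or len(bgs) < n_per_class:
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene = generate_scene(params, seed=scene_seed)
        H, W = scene.image.shape[:2]
        slices = ndi.find_objects(scene.instance_labels)
        for sl in slices:
            if sl is None or len(ears) >= n_per_class:
                continue
            ys, xs = sl
            my = int(margin * (ys.stop - ys.start)) + 1
            mx = int(margin * (xs.stop - xs.start)) + 1
            y0, y1 = max(0, ys.start - my), min(H, ys.stop + my)
            x0, x1 = max(0, xs.start - mx), min(W, xs.stop + mx)
            crop = scene.image[y0:y1, x0:x1]
            mask = scene.ear_mask[y0:y1, x0:x1]
            ears.append(Patch(crop, mask, EAR, origin=(scene_seed, y0, x0, y1, x1)))
        # background crops: rejection-sample ear-free boxes
        tries = 0
        while len(bgs) < n_per_class and tries < 200:
            tries += 1
            bh = int(rng.uniform(24, 48))
            bw = int(rng.uniform(24, 48))
            y0 = int(rng.uniform(0, H - bh))
            x0 = int(rng.uniform(0, W - bw))
            if scene.ear_mask[y0:y0 + bh, x0:x0 + bw].any():
                continue
            crop = scene.image[y0:y0 + bh, x0:x0 + bw]
            bgs.append(Patch(crop, np.zeros((bh, bw), np.uint8), BACKGROUND,
                             origin=(scene_seed, y0, x0, y0 + bh, x0 + bw)))
        scene_i += 1
        if scene_i > 50 * (1 + n_per_class // max(1, params.n_ears)):
            raise RuntimeError("could not collect enough patches; relax parameters")
    return PatchSet(ears[:n_per_class] + bgs[:n_per_class])
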