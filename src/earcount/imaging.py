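"""Shared image primitives: validation, color conversions, gamma, median filter, I/O.

All images are numpy arrays. An RGB image is ``(H, W, 3) uint8``; a grayscale
image is ``(H, W) uint8``; a binary mask is ``(H, W)`` of {0, 1} (any integer or
bool dtype is accepted where a mask is expected). CIELAB images are ``(H, W, 3)``
float with L in [0, 100], following the sRGB/D65 convention.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage import color as skcolor

__all__ = [
    "as_rgb",
    "as_gray",
    "to_grayscale",
    "to_cielab",
    "apply_gamma",
    "median_filter",
    "read_image",
    "write_image",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W, 3) uint8`` RGB image.

    Raises ``ValueError`` on empty or mis-shaped input. Float inputs in [0, 255]
    are rounded; values outside [0, 255] are rejected.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        a = np.asarray(arr, dtype=float)
        if a.min() < 0 or a.max() > 255:
            raise ValueError("RGB intensities must lie in [0, 255]")
        arr = np.rint(a).astype(np.uint8)
    return arr


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W) uint8`` grayscale image."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected (H, W) grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        a = np.asarray(arr, dtype=float)
        if a.min() < 0 or a.max() > 255:
            raise ValueError("gray intensities must lie in [0, 255]")
        arr = np.rint(a).astype(np.uint8)
    return arr


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance-weighted RGB -> gray (0.299 R + 0.587 G + 0.114 B, rounded)."""
    rgb = as_rgb(img).astype(np.float64)
    w = np.asarray(GRAY_WEIGHTS)
    return np.rint(rgb @ w).clip(0, 255).astype(np.uint8)


def to_cielab(img: np.ndarray) -> np.ndarray:
    """sRGB (D65) -> CIELAB. Returns float ``(H, W, 3)`` with L in [0, 100]."""
    rgb = as_rgb(img)
    return skcolor.rgb2lab(rgb)


def apply_gamma(img: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma-encode an RGB image: ``out = round(255 * (in/255)**(1/gamma))``.

    ``gamma > 1`` brightens mid-tones, ``gamma < 1`` darkens them; 0 and 255
    are fixed points for every gamma.
    """
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be a positive real, got {gamma!r}")
    rgb = as_rgb(img)
    # 256-entry LUT: exact and cheap for 8-bit input.
    lut = np.rint(255.0 * (np.arange(256) / 255.0) ** (1.0 / gamma)).astype(np.uint8)
    return lut[rgb]


def median_filter(img: np.ndarray, window: int = 7) -> np.ndarray:
    """Sliding-window median with reflection at the borders.

    Every output pixel is the median of its ``window x window`` neighborhood
    (values sorted, middle taken — the window size is odd so the median is an
    element of the window). Works on grayscale images and on binary masks, for
    which it acts as a majority-vote denoiser. Shape and dtype are preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return ndi.median_filter(arr, size=window, mode="reflect")


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an ``(H, W, 3) uint8`` RGB image.

    Grayscale files are replicated to three channels; an alpha channel is dropped.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return as_rgb(arr)


def write_image(path, img: np.ndarray) -> None:
    """Write an RGB or grayscale image as an 8-bit file (format from extension)."""
    import imageio.v3 as iio

    arr = np.asarray(img)
    arr = as_gray(arr) if arr.ndim == 2 else as_rgb(arr)
    iio.imwrite(path, arr)
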