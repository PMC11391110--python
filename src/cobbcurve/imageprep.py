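"""Radiograph I/O, size standardization, and contrast enhancement.

Working convention: every image is standardized to a fixed 900x1900-pixel
frame by an aspect-preserving rescale followed by symmetric zero-padding
(letterboxing).  Stretching to the frame would distort every subsequent
angle by the anisotropy factor, so it is never done; the recorded scale and
pad offsets let detections be mapped back to original pixel coordinates.

Contrast enhancement mimics the window/level adjustment a radiologist
applies in a DICOM viewer before measuring.  Three deterministic methods
are provided: percentile windowing (default), gamma correction, and CLAHE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from PIL import Image
from skimage import exposure, transform

__all__ = [
    "STANDARD_SIZE",
    "StandardImage",
    "read_image",
    "write_image",
    "standardize",
    "enhance_contrast",
]

#: Default working frame, (width, height) in pixels.
STANDARD_SIZE = (900, 1900)


@dataclass
class StandardImage:
    """A grayscale image with intensities in [0, 1] plus the geometry
    linking it back to the original pixel grid.

    ``pixels`` is a (H, W) float array.  ``pad_offsets`` is (left, top) in
    pixels of the letterbox border added by :func:`standardize`; ``scale``
    is the isotropic resize factor applied before padding.
    """

    pixels: np.ndarray
    original_size: Tuple[int, int]
    standard_size: Tuple[int, int]
    pad_offsets: Tuple[int, int] = (0, 0)
    scale: float = 1.0

    @property
    def size(self) -> Tuple[int, int]:
        """(width, height) of the pixel array."""
        h, w = self.pixels.shape
        return (w, h)

    def to_standard_coords(self, x: float, y: float) -> Tuple[float, float]:
        """Map a point from original to standardized pixel coordinates
        (pixel-center convention)."""
        left, top = self.pad_offsets
        return (
            (x + 0.5) * self.scale - 0.5 + left,
            (y + 0.5) * self.scale - 0.5 + top,
        )

    def to_original_coords(self, x: float, y: float) -> Tuple[float, float]:
        """Inverse of :meth:`to_standard_coords`."""
        left, top = self.pad_offsets
        return (
            (x - left + 0.5) / self.scale - 0.5,
            (y - top + 0.5) / self.scale - 0.5,
        )


def _from_array(arr: np.ndarray) -> StandardImage:
    h, w = arr.shape
    return StandardImage(pixels=arr, original_size=(w, h), standard_size=(w, h))


def as_standard_image(obj) -> StandardImage:
    """Wrap a bare 2D array as a :class:`StandardImage`; pass through
    existing instances."""
    if isinstance(obj, StandardImage):
        return obj
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D grayscale array")
    return _from_array(arr)


def read_image(path) -> StandardImage:
    """Read an 8/16-bit grayscale PNG or TIFF, rescaling intensities to
    [0, 1] by the container bit depth.  RGB inputs are converted by
    channel-average luminance."""
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA"):
                arr = np.asarray(im.convert("RGB"), dtype=float).mean(axis=2) / 255.0
            elif mode == "L":
                arr = np.asarray(im, dtype=float) / 255.0
            elif mode in ("I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=float) / 65535.0
            elif mode == "I":
                arr = np.asarray(im, dtype=float)
                arr = arr / 65535.0 if arr.max() > 255 else arr / 255.0
            elif mode == "F":
                arr = np.asarray(im, dtype=float)
            else:
                raise OSError(f"unsupported image mode {mode!r} in {path}")
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return _from_array(np.clip(arr, 0.0, 1.0))


def write_image(image, path, bit_depth: int = 8) -> None:
    """Write intensities in [0, 1] as an 8-bit PNG (default) or 16-bit
    TIFF; quantization happens only here."""
    arr = as_standard_image(image).pixels
    if bit_depth == 8:
        Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(path)
    elif bit_depth == 16:
        data = (np.clip(arr, 0, 1) * 65535).round().astype(np.uint16)
        Image.fromarray(data).save(path, format="TIFF")
    else:
        raise ValueError("bit_depth must be 8 or 16")


def standardize(image, standard_size: Tuple[int, int] = STANDARD_SIZE) -> StandardImage:
    """Aspect-preserving rescale + symmetric zero-padding to the working
    frame (default 900x1900).  Idempotent: an image already at the target
    size passes through unchanged."""
    img = as_standard_image(image)
    tw, th = standard_size
    h, w = img.pixels.shape
    if h == 0 or w == 0:
        raise ValueError("zero-area image cannot be standardized")
    if (w, h) == (tw, th):
        return replace(img, standard_size=(tw, th))
    scale = min(tw / w, th / h)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = transform.resize(
        img.pixels, (nh, nw), order=1, anti_aliasing=scale < 1.0, preserve_range=True
    )
    left, top = (tw - nw) // 2, (th - nh) // 2
    canvas = np.zeros((th, tw), dtype=float)
    canvas[top : top + nh, left : left + nw] = resized
    return StandardImage(
        pixels=canvas,
        original_size=img.original_size,
        standard_size=(tw, th),
        pad_offsets=(left, top),
        scale=scale * img.scale,
    )


def enhance_contrast(image, method: str = "window", **params) -> StandardImage:
    """Deterministic contrast enhancement; output stays in [0, 1].

    ``window``: linear stretch of the [lo, hi] intensity percentiles
    (defaults 2, 98) to [0, 1] with clipping.  ``gamma``: pixel**gamma.
    ``clahe``: contrast-limited adaptive histogram equalization over an
    8x8 tile grid with configurable ``clip_limit``.
    """
    img = as_standard_image(image)
    px = img.pixels
    if method == "window":
        lo = params.get("lo", 2.0)
        hi = params.get("hi", 98.0)
        if lo >= hi:
            raise ValueError(f"window percentiles need lo < hi, got lo={lo}, hi={hi}")
        p_lo, p_hi = np.percentile(px, [lo, hi])
        if p_hi - p_lo < 1e-12:  # flat image: no contrast to stretch
            out = px.copy()
        else:
            out = np.clip((px - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    elif method == "gamma":
        gamma = params.get("gamma", 1.0)
        if gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {gamma}")
        out = np.clip(px, 0.0, 1.0) ** gamma
    elif method == "clahe":
        clip = params.get("clip_limit", 0.01)
        h, w = px.shape
        kernel = (max(1, h // 8), max(1, w // 8))
        out = exposure.equalize_adapthist(
            np.clip(px, 0.0, 1.0), kernel_size=kernel, clip_limit=clip
        )
    else:
        raise ValueError(
            f"unknown enhancement method {method!r}; supported: window, gamma, clahe"
        )
    return replace(img, pixels=out)
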