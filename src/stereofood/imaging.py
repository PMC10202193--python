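"""Image loading and standardization.

The capture protocol assumes hand-held smartphone photos; before any
geometry runs, each image is contrast-enhanced with CLAHE and resized to a
fixed 600 rows x 800 columns working resolution.  All pixel coordinates in
the package are 0-based, x -> right (column), y -> down (row), with
sampling at pixel centers.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError
from skimage import exposure
from skimage.color import rgb2ycbcr, ycbcr2rgb

from .errors import InputError, ParameterError

#: Fixed working resolution (rows, cols) every input pair is resized to.
STANDARD_SHAPE = (600, 800)


def load_image(path) -> np.ndarray:
    """Load a PNG/JPEG file as an RGB uint8 array of shape (H, W, 3).

    EXIF orientation tags are honored.  Raises :class:`InputError` for
    missing, truncated or undecodable files.
    """
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InputError(f"image {path!r} decoded to invalid shape {arr.shape}")
    return arr


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma (ITU-R 601) of an RGB uint8 image, as uint8; gray passes through."""
    if img.ndim == 2:
        return img
    f = img.astype(np.float64)
    y = 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def enhance_clahe(img: np.ndarray, clip_limit: float = 2.0,
                  tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    For color input the equalization runs on the luminance channel of a
    luma/chroma decomposition and chroma is left untouched, so hue is
    preserved for the reference-card detection.  ``clip_limit`` follows the
    common CLAHE convention (contrast-limiting slope, ~2-4 typical) and is
    mapped internally onto skimage's normalized clip fraction.

    Dimensions and channel count are unchanged; output stays in [0, 255].
    """
    if clip_limit <= 0:
        raise ParameterError(f"clip_limit must be > 0, got {clip_limit}")
    rows, cols = int(tile_grid[0]), int(tile_grid[1])
    if rows < 1 or cols < 1:
        raise ParameterError(f"tile_grid must be >= (1, 1), got {tile_grid}")
    kernel = (max(1, img.shape[0] // rows), max(1, img.shape[1] // cols))
    clip = min(1.0, clip_limit / 255.0)

    def _run(channel01: np.ndarray) -> np.ndarray:
        return exposure.equalize_adapthist(channel01, kernel_size=kernel,
                                           clip_limit=clip)

    if img.ndim == 2:
        out = _run(img.astype(np.float64) / 255.0)
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)

    ycc = rgb2ycbcr(img)  # Y in [16, 235]
    y01 = np.clip((ycc[..., 0] - 16.0) / 219.0, 0.0, 1.0)
    ycc[..., 0] = _run(y01) * 219.0 + 16.0
    rgb = ycbcr2rgb(ycc)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def resize_standard(img: np.ndarray, shape: tuple[int, int] = STANDARD_SHAPE) -> np.ndarray:
    """Bilinear resize to the fixed working resolution (default 600 x 800).

    Aspect-ratio distortion is accepted: the protocol always targets the
    same landscape geometry, and the camera matrix is rescaled to match
    (see :mod:`stereofood.pipeline`).  Idempotent on already-standard input.
    """
    h, w = int(shape[0]), int(shape[1])
    if img.shape[0] == h and img.shape[1] == w:
        return img.copy()
    pil = Image.fromarray(img)
    return np.asarray(pil.resize((w, h), Image.BILINEAR), dtype=np.uint8)
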