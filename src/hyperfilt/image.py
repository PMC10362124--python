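"""Raster I/O and gray-level preprocessing shared by every filter.

A gray image in this package is a plain 2-D ``numpy.float64`` array whose
intensities are nominally in ``[0, 1]``.  Filter outputs are allowed to leave
that range; :func:`rescale_for_display` maps them back affinely at save or
display time, never silently before metrics are computed.
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GRAY_WEIGHTS",
    "validate_gray",
    "to_gray",
    "load_image",
    "save_image",
    "rescale_for_display",
]

log = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum side length any filter can iterate over.
MIN_SIDE = 3


def validate_gray(img, name: str = "image") -> np.ndarray:
    """Coerce *img* to a valid float64 gray image or raise ``ValueError``.

    Valid means: 2-D, at least 3x3, all pixels finite.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValueError(
            f"{name} must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
        )
    if not np.isfinite(arr).all():
        n_bad = int(np.size(arr) - np.isfinite(arr).sum())
        raise ValueError(f"{name} contains {n_bad} non-finite pixel(s)")
    return arr


def to_gray(rgb) -> np.ndarray:
    """Convert an ``(h, w, 3)`` RGB array to gray with BT.601 luma weights.

    The output is pixelwise within ``[min(R,G,B), max(R,G,B)]`` because the
    weights are a convex combination.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (h, w, 3) array, got shape {arr.shape}")
    return arr @ GRAY_WEIGHTS


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as a float64 gray image in ``[0, 1]``.

    Integer samples are divided by their type maximum; 3-channel images are
    gray-converted; an alpha channel is dropped with a logged warning.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"could not read image file {os.fspath(path)!r}: {exc}") from exc

    arr = np.asarray(raw)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(raw.dtype).max
    else:
        arr = arr.astype(np.float64)

    if arr.ndim == 3:
        if arr.shape[2] == 4:
            log.warning("dropping alpha channel of %s", path)
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = to_gray(arr)
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise OSError(
                f"unsupported channel count {arr.shape[2]} in {os.fspath(path)!r}"
            )
    return validate_gray(arr, name=os.fspath(path))


def save_image(path, img, depth: int = 16) -> None:
    """Write a gray image to *path*, clipped to ``[0, 1]`` and quantized.

    ``depth`` is 8 or 16 bits; 16-bit PNG/TIFF round-trips within 1/65535.
    """
    arr = validate_gray(img)
    if depth == 16:
        out = np.round(np.clip(arr, 0.0, 1.0) * 65535).astype(np.uint16)
    elif depth == 8:
        out = np.round(np.clip(arr, 0.0, 1.0) * 255).astype(np.uint8)
    else:
        raise ValueError(f"depth must be 8 or 16, got {depth}")
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise OSError(f"could not write image file {os.fspath(path)!r}: {exc}") from exc


def rescale_for_display(img) -> np.ndarray:
    """Affinely map an image so min -> 0 and max -> 1.

    A constant image maps to all zeros.  Non-finite pixels are an error
    because the affine map would be meaningless.
    """
    arr = np.asarray(img, dtype=np.float64)
    if not np.isfinite(arr).all():
        n_bad = int(np.size(arr) - np.isfinite(arr).sum())
        raise ValueError(f"cannot rescale: {n_bad} non-finite pixel(s)")
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
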