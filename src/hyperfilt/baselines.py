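"""Classical comparison methods: gradient operators, LoG, Gabor bank,
oriented matched filter.

Each method returns an :class:`EdgeMap` holding the raw nonnegative response
magnitude, the binary mask obtained at a threshold, and the threshold used.
The default "auto" threshold is mean + 1 standard deviation of the
magnitude — scale-free and deterministic, and the same rule the evaluation
module applies to the special-function filters so all methods are scored on
equal footing.

All convolutions use reflective border padding to avoid spurious border
responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

__all__ = [
    "EdgeMap",
    "auto_threshold",
    "gradient_edge",
    "log_edge",
    "gabor_bank",
    "matched_filter",
    "matched_filter_kernels",
]

# Standard unnormalized kernel pairs (x-derivative, y-derivative).
GRADIENT_KERNELS = {
    "sobel": (
        np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64),
        np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64),
    ),
    "prewitt": (
        np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=np.float64),
        np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]], dtype=np.float64),
    ),
    "roberts": (
        np.array([[1, 0], [0, -1]], dtype=np.float64),
        np.array([[0, 1], [-1, 0]], dtype=np.float64),
    ),
}


@dataclass(frozen=True)
class EdgeMap:
    """magnitude: nonnegative response grid; mask: magnitude >= threshold;
    threshold: the scalar actually used."""

    magnitude: np.ndarray
    mask: np.ndarray
    threshold: float


def auto_threshold(magnitude: np.ndarray) -> float:
    """Default binarization level: mean + 1 std of the response."""
    return float(magnitude.mean() + magnitude.std())


def _finalize(magnitude: np.ndarray, threshold) -> EdgeMap:
    thr = auto_threshold(magnitude) if threshold == "auto" else float(threshold)
    return EdgeMap(magnitude=magnitude, mask=magnitude >= thr, threshold=thr)


def _convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(img, kernel, mode="reflect")


def gradient_edge(img, operator: str = "sobel", threshold="auto") -> EdgeMap:
    """First-derivative edge detection with Sobel, Prewitt or Roberts kernels.

    magnitude = sqrt(Gx**2 + Gy**2) of the two unnormalized kernel responses
    (a unit vertical step peaks at 4 under Sobel, 3 under Prewitt).
    """
    arr = np.asarray(img, dtype=np.float64)
    try:
        kx, ky = GRADIENT_KERNELS[operator]
    except KeyError:
        raise ValueError(
            f"unknown operator {operator!r}; choose from {sorted(GRADIENT_KERNELS)}"
        ) from None
    gx = _convolve(arr, kx)
    gy = _convolve(arr, ky)
    return _finalize(np.hypot(gx, gy), threshold)


def log_edge(img, sigma: float = 1.0, threshold="auto") -> EdgeMap:
    """Laplacian-of-Gaussian zero-crossing detection.

    The image is smoothed at *sigma* and the Laplacian taken; a pixel's
    magnitude is the largest jump |L(p) - L(q)| over 4-neighbors q of
    opposite sign (0 where no sign change), so the mask marks strong zero
    crossings.  Impulse noise injects high-frequency energy faster than the
    Gaussian removes it, which is why LoG degrades badly on salt-and-pepper
    images.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    arr = np.asarray(img, dtype=np.float64)
    lap = ndimage.gaussian_laplace(arr, sigma, mode="reflect")
    mag = np.zeros_like(lap)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(lap, shift, axis=axis)
        # roll wraps; neutralize the wrapped slice so borders use only
        # in-image neighbors
        if axis == 0:
            if shift == 1:
                neighbor[0, :] = lap[0, :]
            else:
                neighbor[-1, :] = lap[-1, :]
        else:
            if shift == 1:
                neighbor[:, 0] = lap[:, 0]
            else:
                neighbor[:, -1] = lap[:, -1]
        opposite = lap * neighbor < 0
        jump = np.where(opposite, np.abs(lap - neighbor), 0.0)
        mag = np.maximum(mag, jump)
    return _finalize(mag, threshold)


def gabor_bank(
    img,
    frequencies=(0.1, 0.2),
    orientations: int = 4,
    threshold="auto",
) -> EdgeMap:
    """Maximum modulus response over a bank of zero-DC complex Gabor kernels.

    Frequencies are in cycles/pixel and must lie in (0, 0.5) (Nyquist);
    orientations are spread uniformly over [0, pi).
    """
    arr = np.asarray(img, dtype=np.float64)
    if len(frequencies) < 1 or orientations < 1:
        raise ValueError("need at least one frequency and one orientation")
    for f in frequencies:
        if not 0.0 < f < 0.5:
            raise ValueError(f"frequency must be in (0, 0.5) cycles/pixel, got {f}")
    mag = np.zeros_like(arr)
    for f in frequencies:
        for k in range(orientations):
            theta = np.pi * k / orientations
            kern = gabor_kernel(frequency=f, theta=theta)
            kern = kern - kern.mean()  # force zero DC exactly
            re = _convolve(arr, np.real(kern))
            im = _convolve(arr, np.imag(kern))
            mag = np.maximum(mag, np.hypot(re, im))
    return _finalize(mag, threshold)


def matched_filter_kernels(
    sigma: float = 2.0, length: int = 9, n_orientations: int = 12
) -> list[np.ndarray]:
    """Oriented zero-mean line-detection kernels.

    Each kernel has a Gaussian cross-profile exp(-x'^2 / 2 sigma^2) across a
    straight segment of the given length, is mean-subtracted over its support
    so it sums to zero, and is rotated over n_orientations angles in [0, pi).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if n_orientations < 1:
        raise ValueError(f"n_orientations must be >= 1, got {n_orientations}")
    half = int(np.ceil(max(3.0 * sigma, length / 2.0)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = []
    for k in range(n_orientations):
        # theta is the line direction: theta = 0 detects horizontal lines
        theta = np.pi * k / n_orientations
        along = x * np.cos(theta) + y * np.sin(theta)
        across = -x * np.sin(theta) + y * np.cos(theta)
        support = (np.abs(along) <= length / 2.0) & (np.abs(across) <= 3.0 * sigma)
        kern = np.where(support, np.exp(-(across**2) / (2.0 * sigma**2)), 0.0)
        n_sup = int(support.sum())
        if n_sup == 0:
            raise ValueError("degenerate matched-filter kernel: empty support")
        kern[support] -= kern[support].sum() / n_sup
        if not np.any(kern):
            raise ValueError("degenerate matched-filter kernel: all zero")
        kernels.append(kern)
    return kernels


def matched_filter(
    img,
    sigma: float = 2.0,
    length: int = 9,
    n_orientations: int = 12,
    threshold="auto",
) -> EdgeMap:
    """Oriented matched filtering for bright curvilinear structures.

    magnitude is the pixelwise maximum over orientations of the zero-mean
    kernel responses, floored at 0 (the kernels respond positively to bright
    lines on a dark background).
    """
    arr = np.asarray(img, dtype=np.float64)
    mag = np.full_like(arr, -np.inf)
    for kern in matched_filter_kernels(sigma, length, n_orientations):
        mag = np.maximum(mag, _convolve(arr, kern))
    mag = np.maximum(mag, 0.0)
    return _finalize(mag, threshold)
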