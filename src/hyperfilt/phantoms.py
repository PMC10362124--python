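"""Deterministic synthetic phantoms with analytic ground-truth edge masks.

Real photographs and the near-infrared (NIR) fluorescence image the filters
were designed around are not distributable, so every test surface is
generated here: geometric shape scenes, step edges, and a "tube under
tissue" phantom — a bright elongated blurred bar over a dim textured
background that mimics a dye-filled tube imaged through scattering tissue.

Edge rasterization rule (used by every generator and by edge scoring): a
pixel is an edge pixel iff one of its 4-neighbors carries a different region
label and the pixel's own label is not the background label 0.  Generators
without a background (the step edge) use only nonzero labels, so both sides
of the discontinuity are marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import validate_gray

__all__ = [
    "Phantom",
    "edges_from_labels",
    "make_shapes_phantom",
    "make_step_edge",
    "make_nir_tube_phantom",
]


class GenerationError(RuntimeError):
    """The requested phantom cannot be placed on the given canvas."""


@dataclass(frozen=True)
class Phantom:
    """image: gray image in [0, 1]; edge_mask: boolean ground-truth edge
    grid of the same shape; meta: generator name, parameters and seed."""

    image: np.ndarray
    edge_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def edges_from_labels(labels: np.ndarray, background: int = 0) -> np.ndarray:
    """Apply the package-wide edge rasterization rule to a label grid."""
    lbl = np.asarray(labels)
    differs = np.zeros(lbl.shape, dtype=bool)
    differs[1:, :] |= lbl[1:, :] != lbl[:-1, :]
    differs[:-1, :] |= lbl[:-1, :] != lbl[1:, :]
    differs[:, 1:] |= lbl[:, 1:] != lbl[:, :-1]
    differs[:, :-1] |= lbl[:, :-1] != lbl[:, 1:]
    return differs & (lbl != background)


def make_shapes_phantom(
    h: int = 256, w: int = 256, seed: int = 0, n_shapes: int | None = None
) -> Phantom:
    """Non-overlapping filled rectangles and disks with distinct gray levels.

    3-6 shapes with levels drawn from an even grid over [0.2, 0.9] sit on a
    0.1 background; a 2-pixel clearance separates shapes.  Deterministic
    given the seed.
    """
    if h < 64 or w < 64:
        raise GenerationError(f"canvas must be at least 64x64, got {h}x{w}")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7)) if n_shapes is None else int(n_shapes)
    if not 1 <= n <= 8:
        raise GenerationError(f"n_shapes must be in [1, 8], got {n}")
    levels = rng.permutation(np.linspace(0.2, 0.9, n))
    labels = np.zeros((h, w), dtype=np.int32)
    image = np.full((h, w), 0.1)
    placed = 0
    for _ in range(600):
        if placed == n:
            break
        kind = rng.choice(["rect", "disk"])
        size = int(rng.integers(min(h, w) // 10, min(h, w) // 4))
        r0 = int(rng.integers(2, h - size - 2)) if h - size - 2 > 2 else 2
        c0 = int(rng.integers(2, w - size - 2)) if w - size - 2 > 2 else 2
        rs = slice(max(r0 - 2, 0), min(r0 + size + 2, h))
        cs = slice(max(c0 - 2, 0), min(c0 + size + 2, w))
        if labels[rs, cs].any():
            continue
        if kind == "rect":
            region = np.ones((size, size), dtype=bool)
        else:
            yy, xx = np.mgrid[:size, :size].astype(np.float64)
            rad = (size - 1) / 2.0
            region = (yy - rad) ** 2 + (xx - rad) ** 2 <= rad**2
        block = labels[r0 : r0 + size, c0 : c0 + size]
        block[region] = placed + 1
        img_block = image[r0 : r0 + size, c0 : c0 + size]
        img_block[region] = levels[placed]
        placed += 1
    if placed < n:
        raise GenerationError(
            f"could only place {placed} of {n} shapes on a {h}x{w} canvas"
        )
    return Phantom(
        image=image,
        edge_mask=edges_from_labels(labels),
        meta={"generator": "shapes", "h": h, "w": w, "seed": seed, "n_shapes": n},
    )


def make_step_edge(
    h: int, w: int, column: int, low: float = 0.0, high: float = 1.0
) -> Phantom:
    """Vertical step: *low* left of *column*, *high* from *column* on.

    The edge mask marks the two columns adjacent to the discontinuity
    (both region labels are non-background), even when low == high.
    """
    if not 0 < column < w:
        raise ValueError(f"column must be in (0, {w}), got {column}")
    image = np.empty((h, w))
    image[:, :column] = low
    image[:, column:] = high
    labels = np.ones((h, w), dtype=np.int32)
    labels[:, column:] = 2
    return Phantom(
        image=image,
        edge_mask=edges_from_labels(labels),
        meta={
            "generator": "step",
            "h": h,
            "w": w,
            "column": column,
            "low": low,
            "high": high,
        },
    )


def make_nir_tube_phantom(
    h: int = 256,
    w: int = 256,
    tube_width: int = 12,
    angle: float = 30.0,
    blur_sigma: float = 3.0,
    background: float = 0.1,
    peak: float = 0.9,
    seed: int = 0,
    texture: float = 0.08,
    length_frac: float = 0.6,
) -> Phantom:
    """Bright rotated bar ("tube") on a dim textured background, blurred.

    The bar of the given width and orientation sits at *peak* over a
    *background* carrying mild seeded multiplicative texture; a normalized
    Gaussian blur at *blur_sigma* mimics tissue scattering, so the total
    image energy is conserved by the blur.  The edge mask is the tube
    boundary before blurring.  ``texture=0`` and ``blur_sigma=0`` give an
    exact two-level image.
    """
    if tube_width < 3:
        raise ValueError(f"tube_width must be >= 3, got {tube_width}")
    if not 0.0 <= background < peak <= 1.0:
        raise ValueError(
            f"need 0 <= background < peak <= 1, got {background}, {peak}"
        )
    length = length_frac * min(h, w)
    theta = np.deg2rad(angle)
    y, x = np.mgrid[:h, :w].astype(np.float64)
    yc, xc = (h - 1) / 2.0, (w - 1) / 2.0
    along = (x - xc) * np.cos(theta) + (y - yc) * np.sin(theta)
    across = -(x - xc) * np.sin(theta) + (y - yc) * np.cos(theta)
    # reject geometries whose corners leave the canvas
    half_l, half_w = length / 2.0, tube_width / 2.0
    ext_x = half_l * abs(np.cos(theta)) + half_w * abs(np.sin(theta))
    ext_y = half_l * abs(np.sin(theta)) + half_w * abs(np.cos(theta))
    if ext_x > w / 2.0 - 2 or ext_y > h / 2.0 - 2:
        raise GenerationError(
            f"tube of length {length:.0f} at {angle} deg does not fit {h}x{w}"
        )
    tube = (np.abs(along) <= half_l) & (np.abs(across) <= half_w)

    rng = np.random.default_rng(seed)
    bg = np.full((h, w), background)
    if texture > 0:
        rough = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0, mode="wrap")
        rough /= max(rough.std(), 1e-12)
        bg = bg * (1.0 + texture * rough)
    image = np.where(tube, peak, bg)
    if blur_sigma > 0:
        # wrap mode keeps the normalized kernel's total weight exactly 1,
        # so sum(image) is conserved by the blur
        image = ndimage.gaussian_filter(image, blur_sigma, mode="wrap")
    image = np.clip(image, 0.0, 1.0)
    validate_gray(image)
    labels = tube.astype(np.int32)
    return Phantom(
        image=image,
        edge_mask=edges_from_labels(labels),
        meta={
            "generator": "nir_tube",
            "h": h,
            "w": w,
            "tube_width": tube_width,
            "angle": angle,
            "blur_sigma": blur_sigma,
            "background": background,
            "peak": peak,
            "seed": seed,
            "texture": texture,
            "length_frac": length_frac,
        },
    )
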