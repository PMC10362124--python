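"""Seeded noise injection for the stress tests.

Two families are provided because the degradation studied is described with
mixed vocabulary: "density" and white impulse spots are the signature of
salt-and-pepper noise, so that is the default family; an additive Gaussian
family is available for the literal reading, mapping the density parameter
onto a variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import validate_gray

__all__ = ["NoiseSpec", "add_noise"]

FAMILIES = ("salt_pepper", "gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """family: salt_pepper or gaussian; density: fraction of replaced pixels
    (salt_pepper); variance/mean: additive normal noise (gaussian); seed:
    RNG seed, making injection deterministic."""

    family: str = "salt_pepper"
    density: float = 0.9
    variance: float = 0.01
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")


def add_noise(img, spec: NoiseSpec) -> np.ndarray:
    """Return a noisy copy of *img* according to *spec*.

    salt_pepper: each pixel is independently replaced with probability
    ``density``, half of the replacements by 0 ("pepper") and half by 1
    ("salt").  gaussian: adds ``N(mean, variance)`` and clips to [0, 1].
    Identical specs (seed included) give byte-identical outputs.
    """
    arr = validate_gray(img)
    rng = np.random.default_rng(spec.seed)
    if spec.family == "salt_pepper":
        out = arr.copy()
        replaced = rng.random(arr.shape) < spec.density
        salt = rng.random(arr.shape) < 0.5
        out[replaced & salt] = 1.0
        out[replaced & ~salt] = 0.0
        return out
    # gaussian
    out = arr + rng.normal(spec.mean, np.sqrt(spec.variance), size=arr.shape)
    return np.clip(out, 0.0, 1.0)
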