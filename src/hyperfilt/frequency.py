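"""Fourier-domain filters: the cosh-acosh filter and the sech-asech filter.

Both filters build a real 2-D transfer function ``H`` over the center-shifted
spectrum and multiply it into the image's FFT:

    image --fft2--> g2 --x H--> s --ifft2--> filtered image

The radial coordinate is a distance map around the spectrum center,

    D(i, j) = |i - m1|**n3 + |j - n1|**n3,

with ``m1 = floor(h/2)``, ``n1 = floor(w/2)``.  Each transfer function is a
Chebyshev-type gain in the ratio ``u = D0 / D``:

    cosh-acosh:  CNx  = |cosh(order * acosh(u))| ** n5
                 H    = 1 / (1 + eps**2 * CNx ** n4)
    sech-asech:  CNx2 = |sech(lam * asech(u))| ** nn
                      = |1 / cosh(lam * acosh(1/u))| ** nn
                 H    = 1 / (1 + eps**2 * CNx2 ** 2)

``cosh(N * acosh(u))`` is continued to ``0 <= u < 1`` as ``cos(N * acos(u))``;
the two branches join into the Chebyshev polynomial ``T_N(u)`` at integer N.
The branch structure is what shapes the gains: the cosh branch grows
monotonically (the DC neighbourhood D < D0 is crushed by cosh-acosh, which is
the edge-extraction mechanism), while the cosine branch oscillates in [-1, 1]
and produces the characteristic ripple ("corrugated") bands.

With ``eps = 0`` both transfer functions are identically 1 and the filters
reduce to an FFT round-trip — the identity limit used as an end-to-end test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import validate_gray

__all__ = [
    "FreqGrid",
    "CoshAcoshParams",
    "SechAsechParams",
    "TransferFunction",
    "NumericAssertionError",
    "distance_map",
    "chebyshev_cosh",
    "cosh_acosh_transfer",
    "sech_asech_transfer",
    "apply_frequency_filter",
    "radial_profile",
]

log = logging.getLogger(__name__)

_FMAX = np.finfo(np.float64).max

#: Relative floor applied to D at the grid center so D0/D stays finite.
_CENTER_FLOOR = 1e-12

#: Maximum tolerated |imag| / max|real| after the inverse transform.
_IMAG_TOL = 1e-9


class NumericAssertionError(RuntimeError):
    """An internal numerical contract was violated (e.g. complex residue)."""


@dataclass(frozen=True)
class FreqGrid:
    """Distance map over the center-shifted frequency plane.

    D: the per-bin distance values; (m1, n1_half): the center indices;
    n3: the distance exponent; D0: the reference distance, by default 5% of
    the half-height ``m1`` (in the same units as D).
    """

    D: np.ndarray
    m1: int
    n1_half: int
    n3: float
    D0: float

    @property
    def shape(self):
        return self.D.shape


@dataclass(frozen=True)
class CoshAcoshParams:
    """order: Chebyshev order; n5: power on the cosh base; n4: power inside
    the denominator; eps: ripple constant (eps = 0 gives the all-pass)."""

    order: float = 4.0
    n5: float = 1.0
    n4: float = 2.0
    eps: float = 1.0

    def __post_init__(self):
        if self.order <= 0:
            raise ValueError(f"order must be > 0, got {self.order}")
        if self.eps < 0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")


@dataclass(frozen=True)
class SechAsechParams:
    """lam: Chebyshev order; nn: power on the sech base; eps: ripple
    constant (eps = 0 gives the all-pass)."""

    lam: float = 4.0
    nn: float = 24.0
    eps: float = 1.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.eps < 0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")


@dataclass(frozen=True)
class TransferFunction:
    """Real per-frequency gain grid indexed like the center-shifted spectrum.

    Invariants (enforced by construction): 0 < H <= 1 everywhere, and H is
    symmetric under 180-degree rotation about the center so the inverse
    transform of a real image stays real up to round-off.
    """

    H: np.ndarray
    centered: bool = field(default=True)

    @property
    def shape(self):
        return self.H.shape


def distance_map(h: int, w: int, n3: float = 2.0, d0: float | None = None) -> FreqGrid:
    """Build the distance map ``D = |i - m1|**n3 + |j - n1|**n3``.

    Absolute offsets keep D nonnegative for any n3 and make the map (and
    hence every transfer function) 180-degree rotation symmetric about the
    center ``(floor(h/2), floor(w/2))``.  ``d0`` defaults to ``0.05 * m1``.
    """
    if h < 3 or w < 3:
        raise ValueError(f"grid must be at least 3x3, got {h}x{w}")
    if n3 <= 0:
        raise ValueError(f"n3 must be > 0, got {n3}")
    m1 = h // 2
    n1_half = w // 2
    di = np.abs(np.arange(h, dtype=np.float64) - m1) ** n3
    dj = np.abs(np.arange(w, dtype=np.float64) - n1_half) ** n3
    D = di[:, None] + dj[None, :]
    if d0 is None:
        d0 = 0.05 * m1
    if d0 <= 0:
        raise ValueError(f"D0 must be > 0, got {d0}")
    return FreqGrid(D=D, m1=m1, n1_half=n1_half, n3=float(n3), D0=float(d0))


def chebyshev_cosh(order: float, u) -> np.ndarray:
    """Real continuation of ``cosh(order * acosh(u))`` for ``u >= 0``.

    Returns ``cosh(order*acosh(u))`` for ``u >= 1`` and ``cos(order*acos(u))``
    for ``0 <= u < 1``; at integer order this is the Chebyshev polynomial
    ``T_order(u)``.  Overflow saturates to the largest finite double.
    """
    arr = np.asarray(u, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("chebyshev_cosh requires u >= 0")
    upper = arr >= 1.0
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            upper,
            np.cosh(order * np.arccosh(np.maximum(arr, 1.0))),
            np.cos(order * np.arccos(np.minimum(arr, 1.0))),
        )
    out = np.nan_to_num(out, nan=0.0, posinf=_FMAX, neginf=-_FMAX)
    if np.isscalar(u):
        return float(out)
    return out


def _cosh_acosh_gain(D, d0: float, p: CoshAcoshParams) -> np.ndarray:
    D = np.asarray(D, dtype=np.float64)
    d_safe = np.maximum(D, d0 * _CENTER_FLOOR)
    u = d0 / d_safe
    with np.errstate(over="ignore"):
        cnx = np.abs(chebyshev_cosh(p.order, u)) ** p.n5
        cnx = np.nan_to_num(cnx, nan=0.0, posinf=_FMAX)
        s = p.eps**2 * cnx**p.n4
    s = np.nan_to_num(s, nan=0.0, posinf=_FMAX)
    return 1.0 / (1.0 + s)


def _sech_asech_gain(D, d0: float, p: SechAsechParams) -> np.ndarray:
    D = np.asarray(D, dtype=np.float64)
    d_safe = np.maximum(D, d0 * _CENTER_FLOOR)
    # sech(lam * asech(u)) = 1 / cosh(lam * acosh(1/u)) with u = D0/D
    den = np.abs(chebyshev_cosh(p.lam, d_safe / d0))
    n_zero = int(np.count_nonzero(den == 0.0))
    if n_zero:
        log.warning(
            "sech_asech_transfer: %d zero(s) of the Chebyshev base; "
            "gain saturates to ~0 there",
            n_zero,
        )
    with np.errstate(divide="ignore", over="ignore"):
        base = np.where(den > 0.0, 1.0 / np.where(den > 0.0, den, 1.0), _FMAX)
        cnx2 = base**p.nn
        cnx2 = np.nan_to_num(cnx2, nan=0.0, posinf=_FMAX)
        s = p.eps**2 * cnx2**2
    s = np.nan_to_num(s, nan=0.0, posinf=_FMAX)
    return 1.0 / (1.0 + s)


def cosh_acosh_transfer(grid: FreqGrid, params: CoshAcoshParams | None = None) -> TransferFunction:
    """Transfer function ``H = 1 / (1 + eps^2 * CNx^n4)`` on *grid*.

    At the center (D -> 0, u -> inf) the cosh branch diverges and H -> 0:
    the DC region is suppressed, which is the edge-extraction mechanism.
    ``eps = 0`` yields the all-pass H = 1.
    """
    p = params if params is not None else CoshAcoshParams()
    return TransferFunction(H=_cosh_acosh_gain(grid.D, grid.D0, p))


def sech_asech_transfer(grid: FreqGrid, params: SechAsechParams | None = None) -> TransferFunction:
    """Transfer function ``H = 1 / (1 + eps^2 * CNx2^2)`` on *grid*.

    For D >> D0 the cosh branch makes CNx2 -> 0 and H -> 1 (high spatial
    frequencies pass); for D < D0 the cosine branch makes the gain ripple.
    """
    p = params if params is not None else SechAsechParams()
    return TransferFunction(H=_sech_asech_gain(grid.D, grid.D0, p))


def radial_profile(filter_name: str, params, d_values, d0: float) -> np.ndarray:
    """Evaluate a transfer function's gain on a 1-D grid of distances.

    Used for ripple diagnostics and CSV export; *filter_name* is
    ``"cosh-acosh"`` or ``"sech-asech"``.
    """
    d_values = np.asarray(d_values, dtype=np.float64)
    if filter_name == "cosh-acosh":
        return _cosh_acosh_gain(d_values, d0, params)
    if filter_name == "sech-asech":
        return _sech_asech_gain(d_values, d0, params)
    raise ValueError(f"unknown frequency filter {filter_name!r}")


def apply_frequency_filter(img, tf: TransferFunction) -> np.ndarray:
    """Multiply *tf* into the center-shifted spectrum of *img* and invert.

    The imaginary residue of the inverse transform must be below 1e-9 of the
    real magnitude (guaranteed by the rotation symmetry of H); a larger
    residue raises :class:`NumericAssertionError`.
    """
    arr = validate_gray(img)
    if tf.H.shape != arr.shape:
        raise ValueError(
            f"transfer function shape {tf.H.shape} != image shape {arr.shape}"
        )
    spectrum = np.fft.fftshift(np.fft.fft2(arr))
    out = np.fft.ifft2(np.fft.ifftshift(tf.H * spectrum))
    real = out.real
    imag_max = float(np.abs(out.imag).max())
    scale = float(np.abs(real).max())
    if imag_max > _IMAG_TOL * max(scale, np.finfo(np.float64).tiny):
        raise NumericAssertionError(
            f"imaginary residue {imag_max:.3e} exceeds {_IMAG_TOL:g} of the "
            f"real magnitude {scale:.3e}; is H rotation-symmetric?"
        )
    return real
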