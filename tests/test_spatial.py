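import math

import numpy as np
import pytest

from hyperfilt.metrics import mean_brightness
from hyperfilt.spatial import (
    ExpParams,
    SinhAsinhParams,
    exp_filter,
    sinh_asinh_r_filter,
)


def exp_reference(tt, p):
    """Independent per-pixel scalar loop for the exp transform."""
    out = np.empty_like(tt)
    for i in range(tt.shape[0]):
        for j in range(tt.shape[1]):
            out[i, j] = p.a * math.exp(-p.q * (tt[i, j] - p.b) ** p.n2 / p.c**2)
    return out


def sinh_reference(tt, p):
    """Independent per-pixel scalar loop for the sinh-asinh-r transform."""

    def spow(x, e):
        return math.copysign(abs(x) ** e, x) if x != 0 else 0.0

    out = np.empty_like(tt)
    for i in range(tt.shape[0]):
        for j in range(tt.shape[1]):
            r = tt[i, j] / p.eta
            z = math.sinh(p.a1 * math.asinh(r + p.a2) * spow(r, p.a3))
            out[i, j] = spow(z, p.a4)
    return out


class TestExpFilter:
    def test_pixels_at_offset_map_to_scale(self):
        img = np.full((5, 5), 0.5)
        for n2 in (2, 7, 8, 9):
            out = exp_filter(img, ExpParams(a=3.0, b=0.5, n2=n2))
            assert np.allclose(out, 3.0)

    def test_scalar_oracle(self):
        img = np.full((3, 3), 0.2)
        out = exp_filter(img, ExpParams(a=1, q=2, b=0.5, n2=2, c=1))
        assert np.allclose(out, math.exp(-0.18))

    @pytest.mark.parametrize("n2", [2, 7, 8, 9, 28, 29])
    def test_matches_scalar_reference_loop(self, rng, n2):
        img = rng.random((16, 16))
        p = ExpParams(a=1.3, q=2.0, b=0.5, n2=n2, c=0.9)
        assert np.abs(exp_filter(img, p) - exp_reference(img, p)).max() < 1e-12

    @pytest.mark.parametrize("even,odd", [(8, 9), (28, 29)])
    def test_odd_exponent_brighter_than_adjacent_even(self, shapes_phantom, even, odd):
        img = shapes_phantom.image
        m_even = mean_brightness(exp_filter(img, ExpParams(n2=even)))
        m_odd = mean_brightness(exp_filter(img, ExpParams(n2=odd)))
        assert m_odd > m_even

    def test_even_exponent_bounded_with_max_at_offset(self, rng):
        img = rng.random((16, 16))
        img[4, 7] = 0.5  # force the band center to be attained
        p = ExpParams(a=2.0, q=3.0, b=0.5, n2=8, c=1.0)
        out = exp_filter(img, p)
        assert np.all(out > 0)
        assert np.all(out <= 2.0 + 1e-15)
        assert out[4, 7] == pytest.approx(2.0)

    def test_response_nonincreasing_in_q_for_even_exponent(self, rng):
        img = rng.random((12, 12))
        img[0, 0] = 0.5
        q_grid = [2, 3, 7, 9, 10, 15]
        outs = [exp_filter(img, ExpParams(q=q, n2=8)) for q in q_grid]
        for lo, hi in zip(outs, outs[1:]):
            assert np.all(hi <= lo + 1e-15)

    def test_paper_loop_leaves_two_pixel_border_untouched(self, rng):
        img = rng.random((8, 8))
        out = exp_filter(img, ExpParams(), paper_loop=True)
        full = exp_filter(img, ExpParams())
        assert np.array_equal(out[:2, :], img[:2, :])
        assert np.array_equal(out[:, -1], img[:, -1])
        assert np.array_equal(out[2:-1, 2:-1], full[2:-1, 2:-1])

    def test_odd_exponent_overflow_saturates_finite(self):
        img = np.zeros((3, 3))
        out = exp_filter(img, ExpParams(q=1e4, b=1.0, n2=29, c=1e-3))
        assert np.isfinite(out).all()

    @pytest.mark.parametrize(
        "kwargs", [{"n2": 0}, {"n2": 2.5}, {"c": 0.0}, {"q": -1.0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExpParams(**kwargs)


class TestSinhAsinhRFilter:
    def test_zero_pixels_map_to_zero(self):
        img = np.zeros((4, 4))
        out = sinh_asinh_r_filter(img, SinhAsinhParams(a2=0.7, a3=3.0))
        assert np.array_equal(out, np.zeros((4, 4)))

    def test_identity_composition_at_unit_constants(self):
        img = np.ones((3, 3))
        out = sinh_asinh_r_filter(img, SinhAsinhParams(eta=1, a1=1, a2=0, a3=1, a4=1))
        assert np.allclose(out, 1.0)

    def test_scalar_oracle(self):
        img = np.full((3, 3), 0.3)
        p = SinhAsinhParams(eta=0.5, a1=2, a2=0.1, a3=2, a4=1)
        expected = math.sinh(2 * math.asinh(0.7) * 0.36)
        assert np.allclose(sinh_asinh_r_filter(img, p), expected)

    @pytest.mark.parametrize("a3", [2.0, 4.0, 5.0])
    def test_matches_scalar_reference_loop(self, rng, a3):
        img = rng.random((16, 16))
        p = SinhAsinhParams(eta=0.8, a1=1.5, a2=0.1, a3=a3, a4=1.2)
        assert np.abs(sinh_asinh_r_filter(img, p) - sinh_reference(img, p)).max() < 1e-12

    def test_negative_r_with_fractional_a3_stays_real(self):
        img = np.full((3, 3), 0.25)
        out = sinh_asinh_r_filter(img, SinhAsinhParams(eta=-1.0, a3=1.5))
        assert np.isrealobj(out) and np.isfinite(out).all()

    def test_permutation_equivariance(self, rng):
        img = rng.random((6, 6))
        perm = rng.permutation(36)
        p = SinhAsinhParams(a3=2.5, a4=0.7)
        direct = sinh_asinh_r_filter(img, p).ravel()[perm]
        permuted_img = img.ravel()[perm].reshape(6, 6)
        assert np.allclose(sinh_asinh_r_filter(permuted_img, p).ravel(), direct)

    @pytest.mark.parametrize(
        "kwargs", [{"eta": 0.0}, {"a3": 0.0}, {"a3": -1.0}, {"a4": 0.0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SinhAsinhParams(**kwargs)
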