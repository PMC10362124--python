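import numpy as np
import pytest

from hyperfilt.frequency import (
    CoshAcoshParams,
    SechAsechParams,
    TransferFunction,
    apply_frequency_filter,
    chebyshev_cosh,
    cosh_acosh_transfer,
    distance_map,
    radial_profile,
    sech_asech_transfer,
)


def chebyshev_recurrence(n, u):
    """Brute-force Chebyshev polynomial via T0=1, T1=u, T_{k+1}=2u T_k - T_{k-1}."""
    t_prev, t = np.ones_like(u), u.copy()
    if n == 0:
        return t_prev
    for _ in range(n - 1):
        t_prev, t = t, 2 * u * t - t_prev
    return t


def rotate_about_center(H, m1, n1):
    h, w = H.shape
    return H[(2 * m1 - np.arange(h)) % h][:, (2 * n1 - np.arange(w)) % w]


class TestDistanceMap:
    def test_center_is_zero_and_unit_offset(self):
        g = distance_map(8, 8, n3=2)
        assert g.D[g.m1, g.n1_half] == 0.0
        assert g.D[g.m1, g.n1_half + 1] == 1.0

    def test_corner_oracle(self):
        g = distance_map(8, 8, n3=2)
        assert g.D[0, 0] == 32.0  # 16 + 16 from center (4, 4)

    def test_nonnegative_for_odd_exponent(self):
        g = distance_map(9, 7, n3=3)
        assert np.all(g.D >= 0)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError, match="n3"):
            distance_map(8, 8, n3=0)

    def test_default_reference_distance_is_5pct_of_half_height(self):
        g = distance_map(256, 256)
        assert g.D0 == pytest.approx(0.05 * 128)


class TestChebyshevCosh:
    def test_unit_argument_gives_one(self):
        for order in (1, 2.5, 4, 7):
            assert chebyshev_cosh(order, 1.0) == pytest.approx(1.0)

    def test_order_one_is_identity(self):
        assert chebyshev_cosh(1, 0.5) == pytest.approx(0.5)

    def test_polynomial_oracle_t3_at_2(self):
        assert chebyshev_cosh(3, 2.0) == pytest.approx(26.0)  # 4*8 - 3*2

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_matches_recurrence_on_both_branches(self, order):
        u = np.linspace(0.0, 3.0, 301)
        expected = chebyshev_recurrence(order, u)
        assert np.abs(chebyshev_cosh(order, u) - expected).max() < 1e-9

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_cosh(2, -0.1)


class TestTransferFunctions:
    def test_gain_at_reference_distance(self):
        eps = 0.7
        hc = radial_profile("cosh-acosh", CoshAcoshParams(eps=eps), [6.4], d0=6.4)
        hs = radial_profile("sech-asech", SechAsechParams(eps=eps), [6.4], d0=6.4)
        assert hc[0] == pytest.approx(1 / (1 + eps**2))
        assert hs[0] == pytest.approx(1 / (1 + eps**2))

    def test_dc_region_suppressed_by_cosh_acosh(self):
        g = distance_map(64, 64)
        H = cosh_acosh_transfer(g).H
        assert H[g.m1, g.n1_half] < 1e-6

    def test_high_frequencies_pass_sech_asech(self):
        h = radial_profile("sech-asech", SechAsechParams(), [1e6], d0=6.4)
        assert h[0] == pytest.approx(1.0)

    def test_eps_zero_is_all_pass(self):
        g = distance_map(32, 48)
        assert np.array_equal(cosh_acosh_transfer(g, CoshAcoshParams(eps=0)).H, 1.0 + np.zeros(g.shape))
        assert np.array_equal(sech_asech_transfer(g, SechAsechParams(eps=0)).H, 1.0 + np.zeros(g.shape))

    @pytest.mark.parametrize("odd_shape", [(33, 32), (31, 45)])
    def test_contracts_on_odd_shapes(self, rng, odd_shape):
        g = distance_map(*odd_shape)
        for tf in (cosh_acosh_transfer(g), sech_asech_transfer(g)):
            assert np.all(tf.H > 0) and np.all(tf.H <= 1)
            assert np.allclose(tf.H, rotate_about_center(tf.H, g.m1, g.n1_half))
            out = apply_frequency_filter(rng.random(odd_shape), tf)
            assert np.isrealobj(out)

    def test_random_parameter_sets_stay_bounded_and_symmetric(self, rng):
        g = distance_map(40, 40)
        for _ in range(10):
            pc = CoshAcoshParams(
                order=rng.uniform(0.5, 8),
                n5=rng.uniform(0.1, 30),
                n4=rng.uniform(0.5, 4),
                eps=rng.uniform(0.01, 3),
            )
            ps = SechAsechParams(
                lam=rng.uniform(0.5, 8),
                nn=rng.uniform(1, 200),
                eps=rng.uniform(0.01, 3),
            )
            for tf in (cosh_acosh_transfer(g, pc), sech_asech_transfer(g, ps)):
                assert np.all(tf.H > 0) and np.all(tf.H <= 1)
                assert np.allclose(tf.H, rotate_about_center(tf.H, g.m1, g.n1_half))


class TestRippleStructure:
    def test_sech_asech_oscillates_below_reference_distance(self):
        d0 = 6.4
        d = np.linspace(0.02 * d0, 0.999 * d0, 400)
        prof = radial_profile("sech-asech", SechAsechParams(lam=3, nn=2, eps=1), d, d0)
        sign = np.sign(np.diff(prof))
        sign = sign[sign != 0]
        assert np.sum(sign[:-1] * sign[1:] < 0) >= 2

    def test_cosh_acosh_monotone_on_cosh_branch(self):
        d0 = 6.4
        d = np.linspace(0.02 * d0, 0.999 * d0, 400)
        prof = radial_profile("cosh-acosh", CoshAcoshParams(order=4), d, d0)
        assert np.all(np.diff(prof) >= -1e-15)


class TestApplyFrequencyFilter:
    def test_all_pass_identity(self, rng):
        img = rng.random((32, 32))
        tf = TransferFunction(H=np.ones((32, 32)))
        assert np.abs(apply_frequency_filter(img, tf) - img).max() < 1e-10

    def test_annihilator(self, rng):
        img = rng.random((16, 16))
        tf = TransferFunction(H=np.zeros((16, 16)))
        assert np.allclose(apply_frequency_filter(img, tf), 0.0)

    def test_dc_only_indicator_extracts_mean(self, rng):
        img = rng.random((24, 20))
        H = np.zeros((24, 20))
        H[12, 10] = 1.0  # center-shifted DC bin
        out = apply_frequency_filter(img, TransferFunction(H=H))
        assert np.allclose(out, img.mean(), atol=1e-12)

    def test_linearity(self, rng):
        a_img, b_img = rng.random((32, 32)), rng.random((32, 32))
        tf = cosh_acosh_transfer(distance_map(32, 32))
        lhs = apply_frequency_filter(2.0 * a_img + 0.5 * b_img, tf)
        rhs = 2.0 * apply_frequency_filter(a_img, tf) + 0.5 * apply_frequency_filter(
            b_img, tf
        )
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_end_to_end_identity_at_eps_zero(self, small_phantom):
        img = small_phantom.image
        g = distance_map(*img.shape)
        for tf in (
            cosh_acosh_transfer(g, CoshAcoshParams(eps=0)),
            sech_asech_transfer(g, SechAsechParams(eps=0)),
        ):
            assert np.abs(apply_frequency_filter(img, tf) - img).max() < 1e-8

    def test_shape_mismatch_rejected(self, rng):
        tf = TransferFunction(H=np.ones((8, 8)))
        with pytest.raises(ValueError, match="shape"):
            apply_frequency_filter(rng.random((9, 8)), tf)
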