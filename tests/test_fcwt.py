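"""Morlet window, scale grid, and fast-vs-naive transform equivalence."""

import numpy as np
import pytest
from scipy.integrate import quad

from henspec import fcwt
from henspec.fcwt import (
    SQRT_2PI,
    MorletConfig,
    fcwt_transform,
    freq_window,
    make_scales,
    morlet_hat,
    naive_cwt,
    to_feature_map,
)


def _rel_dev(W_fast, W_ref):
    return np.max(np.abs(W_fast - W_ref)) / np.max(np.abs(W_ref))


class TestMorletHat:
    def test_peak_value(self):
        assert morlet_hat(8.0, 8.0) == pytest.approx(SQRT_2PI)
        assert SQRT_2PI == pytest.approx(2.50663, abs=1e-5)

    def test_gaussian_tails(self):
        assert morlet_hat(18.0, 8.0) < 1e-8 * SQRT_2PI
        assert morlet_hat(-2.0, 8.0) < 1e-8 * SQRT_2PI

    def test_matches_quadrature_fourier_transform_of_mother(self):
        """psi_hat equals the numerically integrated FT of e^{i w0 t} e^{-t^2/2}."""
        w0 = 8.0
        t = np.linspace(-12, 12, 20001)
        psi = np.exp(1j * w0 * t) * np.exp(-(t**2) / 2)
        for w in (6.0, 7.5, 8.0, 8.5, 10.0):
            ft = np.trapezoid(psi * np.exp(-1j * w * t), t)
            assert abs(ft - morlet_hat(w, w0)) / SQRT_2PI < 1e-3
            assert abs(ft.imag) < 1e-6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MorletConfig(omega0=3.0)
        cfg = MorletConfig()
        assert cfg.omega0 == 8.0 and cfg.amplitude == pytest.approx(SQRT_2PI)


class TestFreqWindow:
    def test_closed_form(self):
        assert freq_window(8.0) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_quadrature_oracle(self):
        """RMS width of |psi_hat|^2 about w0 by numerical integration."""
        w0 = 8.0
        power = lambda w: morlet_hat(w, w0) ** 2
        num = quad(lambda w: (w - w0) ** 2 * power(w), w0 - 12, w0 + 12)[0]
        den = quad(power, w0 - 12, w0 + 12)[0]
        assert np.sqrt(num / den) == pytest.approx(freq_window(w0), abs=1e-6)

    def test_daughter_window_scales_inversely(self):
        """Width of the scale-a daughter |psi_hat(a w)|^2 is freq_window()/a."""
        w0, a = 8.0, 4.0
        power = lambda w: morlet_hat(a * w, w0) ** 2
        c = w0 / a
        num = quad(lambda w: (w - c) ** 2 * power(w), c - 4, c + 4)[0]
        den = quad(power, c - 4, c + 4)[0]
        assert np.sqrt(num / den) == pytest.approx(freq_window(w0) / a, rel=1e-6)


class TestMakeScales:
    def test_endpoints(self):
        np.testing.assert_allclose(make_scales(5, 6, 2).scales, [32.0, 64.0])

    def test_log_midpoint(self):
        np.testing.assert_allclose(
            make_scales(5, 6, 3).scales, [32.0, 2**5.5, 64.0], rtol=1e-12
        )
        assert make_scales(5, 6, 3).scales[1] == pytest.approx(45.2548, abs=1e-4)

    def test_default_grid_has_200_scales(self):
        sc = fcwt.default_scales()
        assert sc.n == 200
        assert sc.scales[0] == pytest.approx(32.0)
        assert sc.scales[-1] == pytest.approx(64.0)
        assert np.allclose(np.diff(np.log2(sc.scales)), np.log2(sc.scales[1] / sc.scales[0]))

    @pytest.mark.parametrize("args", [(5, 6, 1), (6, 5, 3), (5, 5, 3)])
    def test_parameter_errors(self, args):
        with pytest.raises(ValueError):
            make_scales(*args)


class TestTransform:
    def test_zero_signal_gives_zero_coefficients(self):
        W = fcwt_transform(np.zeros(64), make_scales(1, 3, 5)).W
        assert np.all(W == 0)

    def test_agrees_with_naive_oracle(self):
        """Max relative deviation < 1e-6 over 20 seeded signals, length <= 128."""
        sc = make_scales(2, 5, 12)
        worst = 0.0
        for s in range(20):
            rng = np.random.default_rng(900 + s)
            L = int(rng.integers(32, 129))
            x = rng.standard_normal(L)
            worst = max(worst, _rel_dev(fcwt_transform(x, sc).W, naive_cwt(x, sc).W))
        assert worst < 1e-6

    def test_default_geometry_200_by_300(self):
        x = np.random.default_rng(0).random(300)
        coeffs = fcwt_transform(x)
        assert coeffs.W.shape == (200, 300)
        assert to_feature_map(coeffs).shape == (200, 300)

    def test_linearity(self):
        sc = make_scales(2, 4, 6)
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        lhs = fcwt_transform(2.5 * x - 1.5 * y, sc).W
        rhs = 2.5 * fcwt_transform(x, sc).W - 1.5 * fcwt_transform(y, sc).W
        assert _rel_dev(lhs, rhs) < 1e-10

    def test_translation_covariance_interior(self):
        """A circular shift of the input shifts coefficient rows (small scales,
        columns away from the padding boundary)."""
        # Scales 4..8: centers w0/a stay below Nyquist and the wavelet
        # time support (~ +-5a) stays inside the interior margin.
        sc = make_scales(2, 3, 5)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(256)
        s = 5
        W0 = fcwt_transform(x, sc).W
        Ws = fcwt_transform(np.roll(x, s), sc).W
        interior = slice(48, 208)
        dev = np.max(np.abs(Ws[:, interior] - W0[:, slice(48 - s, 208 - s)]))
        assert dev / np.max(np.abs(W0)) < 1e-6

    def test_ridge_at_analytic_scale(self):
        """For a cosine of period 16 the maximizing scale is w0*16/(2 pi)."""
        sc = make_scales(4, 5, 33)
        x = np.cos(2 * np.pi * np.arange(256) / 16)
        fmap = to_feature_map(fcwt_transform(x, sc, omega0=8.0))
        ridge_scale = sc.scales[fmap.values[:, 64:192].mean(axis=1).argmax()]
        expected = 8.0 * 16 / (2 * np.pi)  # ~20.37
        step = sc.scales[1] / sc.scales[0]
        assert expected / step <= ridge_scale <= expected * step

    def test_delta_impulse_row_is_sampled_daughter(self):
        """Convolution identity: a unit impulse reproduces the daughter's
        inverse-transformed frequency window at each column."""
        L, t0, a, w0 = 64, 32, 4.0, 8.0
        x = np.zeros(L)
        x[t0] = 1.0
        sc = fcwt.ScaleSequence(scales=np.array([a]), a_exp=2, b_exp=2, n=1)
        row = fcwt_transform(x, sc, omega0=w0).W[0]
        nfft = 2 * 64
        k = np.arange(nfft // 2 + 1)
        xi = 2 * np.pi * k / nfft
        expected = np.array(
            [
                np.sum(morlet_hat(a * xi, w0) * np.exp(2j * np.pi * k * (b - t0) / nfft))
                / nfft
                for b in range(L)
            ]
        )
        np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fcwt_transform(np.ones(4))
        with pytest.raises(ValueError):
            fcwt_transform(np.array([1.0, np.nan] + [0.0] * 30))
        with pytest.raises(ValueError):
            naive_cwt(np.ones(1024))


class TestFeatureMap:
    def test_real_coefficients_give_absolute_values(self):
        sc = make_scales(1, 2, 3)
        coeffs = fcwt.CWTCoefficients(W=np.array([[-1.0, 2.0], [3.0, -4.0]]), scales=sc, omega0=8)
        np.testing.assert_allclose(to_feature_map(coeffs).values, [[1, 2], [3, 4]])

    def test_global_phase_invariance(self):
        sc = make_scales(1, 2, 3)
        rng = np.random.default_rng(5)
        W = rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8))
        m1 = to_feature_map(fcwt.CWTCoefficients(W=W, scales=sc, omega0=8)).values
        m2 = to_feature_map(
            fcwt.CWTCoefficients(W=W * np.exp(1j * 0.7), scales=sc, omega0=8)
        ).values
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_nonnegative(self):
        x = np.random.default_rng(6).standard_normal(64)
        fmap = to_feature_map(fcwt_transform(x, make_scales(2, 4, 6)))
        assert np.all(fmap.values >= 0)
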