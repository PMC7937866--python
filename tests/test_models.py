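"""Closed-form model, perfusion-fraction and cAIC unit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ivimmap as im
from ivimmap import ModelId


class TestAttenuation:
    @pytest.mark.parametrize("model", list(ModelId))
    def test_no_weighting_gives_unity(self, model):
        assert im.attenuation(model, 0.0, 1e-3, 1.0) == 1.0

    @pytest.mark.parametrize(
        "model, b, d, k, expected",
        [
            (ModelId.GAUSSIAN, 1000, 1e-3, 0.0, math.exp(-1.0)),
            (ModelId.KURTOSIS, 600, 1e-3, 1.0, math.exp(-0.54)),
            (ModelId.GAMMA, 600, 1e-3, 1.0, 1.2 ** -3),
        ],
    )
    def test_closed_form_values(self, model, b, d, k, expected):
        assert im.attenuation(model, b, d, k) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model", [ModelId.KURTOSIS, ModelId.GAMMA])
    def test_k_zero_reduces_to_gaussian(self, model):
        b = np.linspace(0, 2500, 20)
        np.testing.assert_array_equal(
            im.attenuation(model, b, 1.2e-3, 0.0),
            im.attenuation(ModelId.GAUSSIAN, b, 1.2e-3),
        )

    @pytest.mark.parametrize("model", [ModelId.KURTOSIS, ModelId.GAMMA])
    @pytest.mark.parametrize("d", [0.5e-3, 1.5e-3, 3e-3])
    def test_continuity_at_small_k(self, model, d):
        b = np.linspace(0, 2500, 26)
        diff = np.abs(
            im.attenuation(model, b, d, 1e-6)
            - im.attenuation(ModelId.GAUSSIAN, b, d)
        )
        assert diff.max() < 1e-5

    def test_kurtosis_gamma_agree_below_600(self):
        # with D*K ~ 1e-3 mm^2/s the two non-Gaussian curves differ by <1%
        # at b = 600 s/mm^2, so lower b-values cannot separate them
        ek = im.attenuation(ModelId.KURTOSIS, 600, 1e-3, 1.0)
        eg = im.attenuation(ModelId.GAMMA, 600, 1e-3, 1.0)
        assert abs(ek - eg) / ek < 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [dict(b=-1, d=1e-3, k=0.0), dict(b=100, d=0.0, k=0.0),
         dict(b=100, d=1e-3, k=-0.5)],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            im.attenuation(ModelId.KURTOSIS, kwargs["b"], kwargs["d"], kwargs["k"])


class TestIvimSignal:
    DIFF = im.DiffusionParams(se0=900.0, d=1e-3, k=0.0)
    PERF = im.PerfusionParams(sv0=100.0, dstar=10e-3, fp=0.1)

    def test_b0_is_total_signal(self):
        for model in ModelId:
            assert im.ivim_signal(0.0, self.DIFF, self.PERF, model) == 1000.0

    def test_no_perfusion_reduces_to_diffusion_term(self):
        b = np.array([0.0, 500.0, 2500.0])
        expected = 900.0 * im.attenuation(ModelId.GAMMA, b, 1e-3, 0.8)
        diff = im.DiffusionParams(se0=900.0, d=1e-3, k=0.8)
        np.testing.assert_allclose(
            im.ivim_signal(b, diff, None, ModelId.GAMMA), expected, rtol=1e-14
        )

    def test_two_compartment_sum(self):
        expected = 900 * math.exp(-1.0) + 100 * math.exp(-10.0)
        got = im.ivim_signal(1000.0, self.DIFF, self.PERF, ModelId.GAUSSIAN)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_when_dstar_exceeds_d(self):
        b = np.linspace(0, 2500, 50)
        s = im.ivim_signal(b, self.DIFF, self.PERF, ModelId.GAUSSIAN)
        assert np.all(np.diff(s) < 0)


class TestPerfusionFraction:
    @pytest.mark.parametrize(
        "sv0, se0, expected", [(0.0, 900.0, 0.0), (100.0, 900.0, 0.1),
                               (250.0, 250.0, 0.5)]
    )
    def test_values(self, sv0, se0, expected):
        assert im.perfusion_fraction(sv0, se0) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            im.perfusion_fraction(0.0, 0.0)


class TestCaic:
    def test_unit_rss_per_point(self):
        # RSS/n = 1 kills the log term: 2P + 2P(P+1)/(n-P-1)
        assert im.caic(im.CaicInput(11, 2, 11.0)) == pytest.approx(5.5)

    def test_three_parameter_value(self):
        assert im.caic(im.CaicInput(11, 3, 11.0)) == pytest.approx(6 + 24 / 7)

    @given(
        n=st.integers(6, 200),
        p=st.integers(2, 4),
        rss=st.floats(1e-6, 1e6),
        alpha=st.floats(1e-4, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_rescaling_shifts_by_2n_log_alpha(self, n, p, rss, alpha):
        a = im.caic(im.CaicInput(n, p, alpha**2 * rss))
        b = im.caic(im.CaicInput(n, p, rss))
        assert a - b == pytest.approx(2 * n * math.log(alpha), abs=1e-8)

    @pytest.mark.parametrize("n, p, rss", [(3, 2, 1.0), (11, 2, 0.0)])
    def test_domain_errors(self, n, p, rss):
        with pytest.raises(ValueError):
            im.caic(im.CaicInput(n, p, rss))


class TestGammaParameterisation:
    @pytest.mark.parametrize(
        "d, k, alpha, beta",
        [(1e-3, 1.0, 3.0, 3000.0), (1e-3, 3.0, 1.0, 1000.0)],
    )
    def test_shape_rate_values(self, d, k, alpha, beta):
        g = im.kurtosis_to_gamma_params(d, k)
        assert (g.alpha, g.beta) == pytest.approx((alpha, beta))

    @given(d=st.floats(1e-4, 3e-3), k=st.floats(0.05, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_through_moments(self, d, k):
        g = im.kurtosis_to_gamma_params(d, k)
        assert g.mean == pytest.approx(d, rel=1e-12)
        # K = 3 sigma^2 / D^2 of the diffusivity distribution
        assert 3 * g.variance / g.mean**2 == pytest.approx(k, rel=1e-12)

    def test_k_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            im.kurtosis_to_gamma_params(1e-3, 0.0)


class TestValidityBounds:
    def test_reference_products(self):
        kb, _ = im.validity_bounds(1.0e-3, 0.5)   # D*K = 0.50e-3
        assert kb == pytest.approx(6000.0)
        kb, _ = im.validity_bounds(1.0e-3, 0.65)  # D*K = 0.65e-3
        assert kb == pytest.approx(3 / 0.65e-3)
        _, gb = im.validity_bounds(1.0e-3, 1.38)  # D*K = 1.38e-3
        assert gb == pytest.approx(27 / (6 * 1.38e-3))

    def test_zero_product_is_flagged_not_fatal(self):
        kb, gb = im.validity_bounds(1e-3, 0.0)
        assert math.isinf(kb) and math.isinf(gb)
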