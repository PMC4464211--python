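"""Waiting-time distribution families: derived constants, densities, CDFs,
moments, and their mutual consistency (quadrature as the independent oracle)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from taurace import (
    FIXTURES,
    DegenerateAError,
    Erlang,
    Exponential,
    Hyperexponential,
    MMWaitingTime,
    ParameterError,
    make_random_valid_params,
    mm_derive,
    mm_mean_rate,
)


class TestMMDerive:
    def test_hand_derived_constants_set_a1(self):
        # k1·S = 50 s⁻¹, σ = 300 s⁻¹ → B = −150, A = sqrt(150²−12500) = 100
        p = mm_derive(k1=1e7, k2=250.0, k_minus1=0.0, S=5e-6)
        assert p.A == pytest.approx(100.0, rel=1e-12)
        assert p.B == pytest.approx(-150.0, rel=1e-12)
        assert p.beta == pytest.approx(-50.0, rel=1e-10)
        assert p.gamma_ == pytest.approx(-250.0, rel=1e-12)
        assert p.alpha == pytest.approx(62.5, rel=1e-12)
        assert p.K_M == pytest.approx(2.5e-5, rel=1e-12)

    def test_dissociation_heavy_set_is_valid(self):
        p = mm_derive(k1=1e7, k2=250.0, k_minus1=2000.0, S=5e-6)
        assert p.A > 0 and p.B < 0
        assert p.gamma_ < p.beta < 0

    def test_signs_and_ordering_of_derived_fields(self):
        p = mm_derive(k1=1.0, k2=1.0, k_minus1=0.0, S=4.0)
        # B²−k1k2S = 6.25−4 = 2.25 > 0: a valid set
        assert p.A == pytest.approx(1.5)
        assert p.alpha > 0

    def test_degenerate_double_root_rejected_distinctly(self):
        # k−1 = 0 and k1·S = k2 exactly → A = 0
        with pytest.raises(DegenerateAError):
            mm_derive(k1=1.0, k2=1.0, k_minus1=0.0, S=1.0)

    @pytest.mark.parametrize("kwargs", [
        dict(k1=-1.0, k2=1.0, k_minus1=0.0, S=1.0),
        dict(k1=1.0, k2=0.0, k_minus1=0.0, S=1.0),
        dict(k1=1.0, k2=1.0, k_minus1=-0.1, S=1.0),
        dict(k1=1.0, k2=1.0, k_minus1=0.0, S=0.0),
    ])
    def test_positivity_violations_are_plain_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError) as err:
            mm_derive(**kwargs)
        assert not isinstance(err.value, DegenerateAError)


class TestPdfCdf:
    def test_mm_density_vanishes_at_zero(self, a1_dist):
        assert a1_dist.pdf(0.0) == 0.0

    def test_mm_density_value(self, a1_dist):
        # α(e^{βτ}−e^{γτ}) at τ=0.01 with α=62.5, β=−50, γ=−250
        expected = 62.5 * (math.exp(-0.5) - math.exp(-2.5))
        assert a1_dist.pdf(0.01) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(32.778, abs=5e-4)

    def test_exponential_density_at_zero_equals_rate(self):
        assert Exponential(0.0078).pdf(0.0) == pytest.approx(0.0078, rel=1e-12)

    def test_cdf_zero_at_origin(self, family_zoo):
        for dist in family_zoo.values():
            assert dist.cdf(0.0) == 0.0

    def test_mm_cdf_approaches_one(self, a1_dist):
        tau = 10.0 / abs(a1_dist.params.beta)
        assert a1_dist.cdf(tau) == pytest.approx(1.0, abs=1e-4)
        assert a1_dist.cdf(30.0 / abs(a1_dist.params.beta)) == pytest.approx(1.0, abs=1e-6)

    def test_mm_cdf_against_quadrature_regression(self, a1_dist):
        # adaptive quadrature of the density is the independent oracle for the
        # closed-form CDF; value frozen as a regression constant
        oracle = quad(a1_dist.pdf, 0.0, 0.024)[0]
        assert a1_dist.cdf(0.024) == pytest.approx(oracle, abs=1e-9)
        assert a1_dist.cdf(0.024) == pytest.approx(0.624126923153914, abs=1e-12)

    def test_negative_tau_strict_by_default(self, family_zoo):
        for dist in family_zoo.values():
            with pytest.raises(ValueError):
                dist.pdf(-0.1)
            with pytest.raises(ValueError):
                dist.cdf(-0.1)
            assert dist.pdf(-0.1, lenient=True) == 0.0
            assert dist.cdf(-0.1, lenient=True) == 0.0

    def test_cdf_derivative_matches_pdf(self, a_set_dist):
        dist = a_set_dist
        taus = np.linspace(0.1, 4.0, 20) * dist.mean()
        h = 1e-7 * dist.mean()
        num = (dist.cdf(taus + h) - dist.cdf(taus - h)) / (2 * h)
        np.testing.assert_allclose(num, dist.pdf(taus), rtol=1e-4)

    def test_cdf_strictly_increasing(self, a_set_dist):
        taus = np.linspace(0.0, 8.0, 200) * a_set_dist.mean()
        vals = a_set_dist.cdf(taus)
        assert np.all(np.diff(vals) > 0)


class TestMoments:
    def test_mm_mean_rate_set_a1(self):
        p = FIXTURES["A1"].params()
        assert mm_mean_rate(p) == pytest.approx(250 * 5e-6 / 3e-5, rel=1e-12)
        assert mm_mean_rate(p) == pytest.approx(41.667, abs=5e-4)

    def test_mm_mean_rate_saturates_at_k2(self):
        # K_M = 3e-5 M: substrate 1e-2 M and 1 M are ~300× and ~30000× K_M
        rates = [mm_mean_rate(mm_derive(1e7, 250.0, 50.0, S)) for S in (1e-2, 1.0)]
        assert rates[0] == pytest.approx(250.0, rel=1e-2)
        assert rates[1] == pytest.approx(250.0, rel=1e-4)

    def test_mm_mean_rate_lactamase_low_substrate(self):
        p = mm_derive(k1=41.0, k2=1920.0, k_minus1=2320.0, S=0.001)
        expected = 1920.0 * 0.001 / (0.001 + (2320.0 + 1920.0) / 41.0)
        assert mm_mean_rate(p) == pytest.approx(expected, rel=1e-12)

    def test_analytic_means(self):
        assert Exponential(0.0078).mean() == pytest.approx(128.205, abs=5e-4)
        assert Erlang(k=2, lam=0.0078).mean() == pytest.approx(256.410, abs=5e-4)
        # single-component mixture degenerates to an exponential
        hyper = Hyperexponential(weights=(1.0,), rates=(2.0,))
        assert hyper.mean() == pytest.approx(0.5, rel=1e-12)
        assert hyper.cdf(0.3) == pytest.approx(Exponential(2.0).cdf(0.3), rel=1e-12)

    @pytest.mark.parametrize("name", ["A1", "A2", "A3", "B1", "B2", "B3"])
    def test_mean_and_variance_against_quadrature(self, name):
        from conftest import quad_mean, quad_second_moment

        dist = FIXTURES[name].dist(S=10.0 if FIXTURES[name].S is None else None)
        m = quad_mean(dist)
        m2 = quad_second_moment(dist)
        assert dist.mean() == pytest.approx(m, rel=1e-8)
        assert dist.second_moment() == pytest.approx(m2, rel=1e-8)
        assert dist.variance() == pytest.approx(m2 - m * m, rel=1e-6)

    def test_reciprocal_integrated_mean_is_the_mm_rate(self, a_set_dist):
        # ergodicity: the single-molecule mean reproduces the ensemble MM law
        p = a_set_dist.params
        m = quad(lambda t: t * a_set_dist.pdf(t), 0, np.inf)[0]
        assert 1.0 / m == pytest.approx(mm_mean_rate(p), rel=1e-6)


class TestNormalization:
    @pytest.mark.parametrize("name", ["A1", "A2", "A3", "B1", "B2", "B3"])
    def test_fixture_sets_integrate_to_one(self, name):
        dist = FIXTURES[name].dist(S=5.0 if FIXTURES[name].S is None else None)
        assert quad(dist.pdf, 0, np.inf)[0] == pytest.approx(1.0, abs=1e-6)

    def test_random_valid_sets_integrate_to_one(self):
        from conftest import quad_norm

        rng = np.random.default_rng(77)
        for _ in range(100):
            dist = MMWaitingTime(make_random_valid_params(rng))
            assert quad_norm(dist) == pytest.approx(1.0, abs=1e-6)

    def test_other_families_integrate_to_one(self, family_zoo):
        for name, dist in family_zoo.items():
            if name == "mm_single_molecule":
                continue
            assert quad(dist.pdf, 0, np.inf)[0] == pytest.approx(1.0, abs=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    k1=st.floats(1e-2, 1e2), k2=st.floats(1e-2, 1e3),
    k_minus1=st.floats(0.0, 1e3), S=st.floats(1e-3, 1e3),
)
def test_mm_invariants_hold_for_arbitrary_valid_parameters(k1, k2, k_minus1, S):
    """For any accepted parameter set: A>0, B<0, γ<β<0, f≥0, F monotone in [0,1],
    and the analytic mean matches the ensemble MM rate law."""
    try:
        p = mm_derive(k1, k2, k_minus1, S)
    except DegenerateAError:
        return
    assert p.A > 0 and p.B < 0 and p.gamma_ < p.beta < 0
    dist = MMWaitingTime(p)
    taus = np.linspace(0, 10, 50) * dist.mean()
    assert np.all(dist.pdf(taus) >= 0)
    F = dist.cdf(taus)
    assert np.all(np.diff(F) >= 0) and F[0] == 0.0 and F[-1] <= 1.0 + 1e-12
    assert 1.0 / dist.mean() == pytest.approx(mm_mean_rate(p), rel=1e-9)


def test_mm_approaches_exponential_in_the_saturated_limit():
    """With k−1=0 and k1·S/k2 = 1e4 the turnover waiting time is dominated by
    the catalytic step: its CDF matches Exp(k2) pointwise to 1e-3."""
    k2 = 250.0
    dist = MMWaitingTime(mm_derive(k1=1e7, k2=k2, k_minus1=0.0, S=1e4 * k2 / 1e7))
    ref = Exponential(k2)
    taus = np.linspace(0.0, 6.0, 100) / k2
    np.testing.assert_allclose(dist.cdf(taus), ref.cdf(taus), atol=1e-3)


def test_invalid_family_parameters_rejected():
    with pytest.raises(ParameterError):
        Exponential(0.0)
    with pytest.raises(ParameterError):
        Erlang(k=0, lam=1.0)
    with pytest.raises(ParameterError):
        Erlang(k=2, lam=-1.0)
    with pytest.raises(ParameterError):
        Hyperexponential(weights=(0.5, 0.4), rates=(1.0, 2.0))  # sums to 0.9
    with pytest.raises(ParameterError):
        Hyperexponential(weights=(0.5, 0.5), rates=(1.0,))
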