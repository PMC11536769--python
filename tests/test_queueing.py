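"""Interarrival transform, renewal function, binomial moments, delay limit."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from genequeue import (GeneModel, ServiceTime, b1_of_t, binomial_moments,
                       delay_cv, delay_distribution, delay_fano,
                       fano_nuclear, fano_total_mrna, first_passage_pdf,
                       interarrival_laplace, phi_helper, renewal_model,
                       service_cdf)
from genequeue.queueing import _b1_phase_type, _phi_reg

from conftest import random_model


def erlang_arrival_model(G, k, **kw):
    defaults = dict(S=1, R=1, k_on=1.0, k_off=0.0, delta=1.0, delta1=1.0)
    defaults.update(kw)
    return GeneModel(G=G, k=tuple([float(k)] * G), **defaults)


class TestInterarrival:
    def test_normalized_at_zero(self, rng):
        for _ in range(20):
            assert interarrival_laplace(random_model(rng))(0.0) == \
                pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("k, expected_alpha", [(0.2, 15.0), (10.0, 0.3)])
    def test_mean_interarrival_constitutive(self, k, expected_alpha):
        phi = interarrival_laplace(erlang_arrival_model(3, k))
        assert phi.alpha == pytest.approx(expected_alpha, rel=1e-12)

    def test_single_state_is_exponential(self):
        m = erlang_arrival_model(1, 2.5)
        phi = interarrival_laplace(m)
        for s in (0.0, 0.3, 2.0, 10.0):
            assert phi(s) == pytest.approx(2.5 / (s + 2.5), rel=1e-12)
        assert phi.cv2 == pytest.approx(1.0, rel=1e-10)

    def test_second_moment_against_quadrature(self, rng):
        m = random_model(rng, G=2)
        phi = interarrival_laplace(m)
        a2, _ = integrate.quad(lambda t: t**2 * first_passage_pdf(m, t),
                               0, 80 * phi.alpha, limit=400)
        assert phi.alpha2 == pytest.approx(a2, rel=1e-6)


class TestFirstPassage:
    def test_density_normalizes(self, rng):
        m = random_model(rng, G=3)
        alpha = interarrival_laplace(m).alpha
        norm, _ = integrate.quad(lambda t: first_passage_pdf(m, t),
                                 0, 50 * alpha, limit=400)
        assert norm == pytest.approx(1.0, abs=1e-6)

    def test_laplace_transform_matches_phi(self, rng):
        m = random_model(rng, G=3)
        phi = interarrival_laplace(m)
        for s in (0.1, 1.0, 10.0):
            val, _ = integrate.quad(
                lambda t: first_passage_pdf(m, t) * math.exp(-s * t),
                0, 300.0, limit=400)
            assert val == pytest.approx(float(phi(s)), abs=1e-6)

    def test_constitutive_single_state_is_exponential_pdf(self):
        m = erlang_arrival_model(1, 1.7)
        t = np.linspace(0.01, 4.0, 30)
        assert np.allclose(first_passage_pdf(m, t),
                           1.7 * np.exp(-1.7 * t), rtol=1e-8)


class TestRenewal:
    def test_starts_at_zero(self, rng):
        rm = renewal_model(interarrival_laplace(random_model(rng)))
        assert rm.R(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_arrivals_linear(self):
        rm = renewal_model(interarrival_laplace(erlang_arrival_model(1, 3.0)))
        assert rm.M == 0
        x = np.linspace(0, 10, 7)
        assert np.allclose(rm.R(x), 3.0 * x)

    def test_long_time_offset_is_c1(self, rng):
        for _ in range(10):
            phi = interarrival_laplace(random_model(rng))
            rm = renewal_model(phi)
            x = 200.0 * phi.alpha
            assert rm.R(x) - x / phi.alpha == pytest.approx(rm.c1, abs=1e-6)
            assert rm.c1 == pytest.approx((phi.cv2 - 1.0) / 2.0, rel=1e-9)

    def test_residues_sum_to_minus_c1(self, rng):
        for _ in range(100):
            rm = renewal_model(interarrival_laplace(random_model(rng)))
            assert np.sum(rm.residues).real == pytest.approx(-rm.c1, abs=1e-8)
            assert abs(np.sum(rm.residues).imag) < 1e-9

    def test_against_brute_force_convolution_sum(self):
        # R(x) = sum_n F^{*n}(x) with Erlang interarrivals: the n-th term
        # is an Erlang(nG, k) CDF
        G, k = 3, 2.0
        rm = renewal_model(interarrival_laplace(erlang_arrival_model(G, k)))
        for x in (0.5, 2.0, 5.0):
            brute = sum(stats.gamma.cdf(x, a=n * G, scale=1 / k)
                        for n in range(1, 200))
            assert rm.R(x) == pytest.approx(brute, abs=1e-10)


class TestServiceTime:
    def test_cdf_limits(self, rng):
        for kind in ("nuclear", "nuclear_plus_cyto"):
            m = random_model(rng)
            st = (ServiceTime.nuclear(m) if kind == "nuclear"
                  else ServiceTime.nuclear_plus_cyto(m))
            assert service_cdf(st, 0.0) == pytest.approx(0.0, abs=1e-12)
            assert service_cdf(st, 400.0 * st.rho) == pytest.approx(1.0, abs=1e-9)

    def test_two_stage_explicit_form(self):
        m = GeneModel(G=1, S=2, R=1, k_on=1, k_off=0, k=(1.0,),
                      delta=1.3, delta1=0.6)
        st = ServiceTime.nuclear(m)
        d, d1 = m.delta, m.delta1
        t = np.linspace(0.0, 8.0, 25)
        expected = (1.0 - d / (d - d1) * np.exp(-d1 * t)
                    + d1 / (d - d1) * np.exp(-d * t))
        assert np.allclose(st.cdf(t), expected, atol=1e-12)

    def test_equal_rates_limit_is_erlang(self):
        m = GeneModel(G=1, S=3, R=1, k_on=1, k_off=0, k=(1.0,),
                      delta=2.0, delta1=2.0)
        st = ServiceTime.nuclear(m)
        t = np.linspace(0.0, 6.0, 20)
        assert np.allclose(st.cdf(t), stats.gamma.cdf(t, a=3, scale=0.5),
                           atol=1e-10)
        # continuity: nearly-equal rates agree with the limit branch
        st2 = ServiceTime(kind="nuclear", S=3, delta=2.0, delta1=2.0 * (1 + 1e-7))
        assert np.allclose(st2.cdf(t), st.cdf(t), atol=1e-6)

    def test_total_service_mean(self, rng):
        m = random_model(rng)
        st = ServiceTime.nuclear_plus_cyto(m)
        expected = (m.S - 1) / m.delta + 1.0 / m.delta1 + m.R / m.lam
        assert st.rho == pytest.approx(expected, rel=1e-12)
        numeric, _ = integrate.quad(lambda t: float(st.sf(t)),
                                    0, 200 * st.rho, limit=400)
        assert numeric == pytest.approx(expected, rel=1e-7)

    def test_total_cdf_matches_convolution_quadrature(self, rng):
        # independent oracle for the nuclear+cytoplasmic service law:
        # Erlang(R, lam) density convolved with the nuclear CDF
        m = random_model(rng, S=2, R=2)
        st = ServiceTime.nuclear_plus_cyto(m)
        stn = ServiceTime.nuclear(m)
        for t in (0.7 * st.rho, 1.5 * st.rho):
            val, _ = integrate.quad(
                lambda x: stats.gamma.pdf(x, a=m.R, scale=1 / m.lam)
                * float(stn.cdf(t - x)), 0, t, limit=300)
            assert float(st.cdf(t)) == pytest.approx(val, abs=1e-8)


class TestPhiHelper:
    def test_zero_time(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 6))
            assert phi_helper(n, float(rng.uniform(0.5, 4)),
                              float(rng.uniform(-2, 2)), 0.0) == \
                pytest.approx(0.0, abs=1e-12)

    def test_matches_defining_integral(self, rng):
        def gamma_lower(n, x):
            return math.gamma(n) * (1 - math.exp(-x) * sum(
                x**i / math.factorial(i) for i in range(n)))

        for _ in range(50):
            n = int(rng.integers(1, 7))
            a = float(rng.uniform(0.2, 5.0))
            b = float(rng.uniform(-3.0, 3.0))
            t = float(rng.uniform(0.1, 8.0))
            direct, _ = integrate.quad(
                lambda x: gamma_lower(n, a * (t - x)) * math.exp(-b * x),
                0, t, limit=300)
            assert phi_helper(n, a, b, t) == pytest.approx(direct, abs=1e-8)

    def test_small_b_continuity(self):
        for n in (1, 3, 5):
            a, t = 1.7, 2.3
            lim = phi_helper(n, a, 0.0, t)
            near = phi_helper(n, a, 1e-7 * a, t)
            assert near == pytest.approx(lim, rel=1e-5)


class TestB1:
    def test_zero_at_origin(self, rng):
        m = random_model(rng)
        rm = renewal_model(interarrival_laplace(m))
        assert b1_of_t(rm, ServiceTime.nuclear(m), 0.0) == \
            pytest.approx(0.0, abs=1e-10)

    def test_approaches_stationary_mean(self, rng):
        for _ in range(5):
            m = random_model(rng)
            phi = interarrival_laplace(m)
            rm = renewal_model(phi)
            st = ServiceTime.nuclear(m)
            t_inf = 80.0 * max(phi.alpha, st.rho)
            assert _b1_phase_type(rm, st, t_inf) == \
                pytest.approx(st.rho / phi.alpha, rel=1e-8)

    def test_closed_form_matches_quadrature(self, rng):
        for _ in range(10):
            m = random_model(rng)
            phi = interarrival_laplace(m)
            rm = renewal_model(phi)
            st = ServiceTime.nuclear(m)
            for t in (0.4 * st.rho, 1.3 * st.rho, 3.0 * st.rho):
                direct, _ = integrate.quad(
                    lambda x: float(rm.dR(x)) * float(st.sf(t - x)),
                    0, t, limit=400)
                assert b1_of_t(rm, st, t) == pytest.approx(direct, abs=1e-6)
                assert _b1_phase_type(rm, st, t) == pytest.approx(direct, abs=1e-8)


class TestBinomialMoments:
    def test_first_moment_is_rho_over_alpha(self, rng):
        m = random_model(rng)
        phi = interarrival_laplace(m)
        st = ServiceTime.nuclear(m)
        b1, _ = binomial_moments(m, st)
        assert b1 == pytest.approx(st.rho / phi.alpha, rel=1e-12)

    def test_poisson_queue_second_moment(self):
        # M/M/infinity: stationary law is Poisson, B2* = B1*^2/2
        m = erlang_arrival_model(1, 2.0, delta1=0.7)
        b1, b2 = binomial_moments(m, ServiceTime.nuclear(m))
        assert b2 == pytest.approx(b1**2 / 2.0, rel=1e-8)

    def test_two_stage_closed_form_agrees(self, rng):
        for _ in range(20):
            m = random_model(rng, S=2)
            ff_closed = fano_nuclear(m)
            ff_quad = fano_nuclear(m, method="quadrature")
            assert ff_closed == pytest.approx(ff_quad, abs=1e-6)


class TestFanoNuclear:
    def test_poisson_limit(self):
        assert fano_nuclear(erlang_arrival_model(1, 3.0, delta1=0.5)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_dual_single_stage_expressions_agree(self, rng):
        from genequeue.queueing import _fano_closed_s1
        for _ in range(100):
            m = random_model(rng, S=1)
            phi = interarrival_laplace(m)
            rm = renewal_model(phi)
            ff_res, ff_phi = _fano_closed_s1(rm, phi, m.delta1)
            assert ff_res == pytest.approx(ff_phi, abs=1e-8)

    def test_fast_processing_limit_reduces_to_single_stage(self, rng):
        for _ in range(20):
            m = random_model(rng, S=2)
            ff_s2_limit = fano_nuclear(m.with_(delta=1e8))
            ff_s1 = fano_nuclear(m.with_(S=1))
            assert ff_s2_limit == pytest.approx(ff_s1, abs=1e-5)

    def test_invariant_under_uniform_rate_rescaling(self, rng):
        m = random_model(rng, S=2)
        c = 7.3
        m2 = m.with_(k_on=m.k_on * c, k_off=m.k_off * c,
                     k=tuple(ki * c for ki in m.k),
                     delta=m.delta * c, delta1=m.delta1 * c)
        assert fano_nuclear(m2) == pytest.approx(fano_nuclear(m), rel=1e-9)


class TestFanoTotal:
    def test_fast_cytoplasm_recovers_nuclear(self, rng):
        m = random_model(rng, S=2, R=1).with_(lam=1e5)
        assert fano_total_mrna(m) == \
            pytest.approx(fano_nuclear(m, method="quadrature"), abs=1e-3)

    def test_first_moment_uses_total_service(self, rng):
        m = random_model(rng)
        st = ServiceTime.nuclear_plus_cyto(m)
        b1, _ = binomial_moments(m, st)
        phi = interarrival_laplace(m)
        expected = ((m.S - 1) / m.delta + 1 / m.delta1 + m.R / m.lam) / phi.alpha
        assert b1 == pytest.approx(expected, rel=1e-12)


class TestDelayLimit:
    def test_pmf_normalized(self):
        for G, kT in ((1, 3.0), (3, 10.0), (4, 55.0)):
            d = delay_distribution(G, kT, 1.0)
            assert d.pmf.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(d.pmf >= 0)

    def test_mean_is_kT_over_G(self):
        for G, k, T in ((2, 5.0, 1.3), (5, 8.0, 0.7)):
            d = delay_distribution(G, k, T)
            assert d.mean() == pytest.approx(k * T / G, rel=1e-9)

    def test_single_state_is_poisson(self):
        d = delay_distribution(1, 4.0, 1.0)
        assert np.allclose(d.pmf, stats.poisson.pmf(d.counts, 4.0), atol=1e-10)

    def test_closed_form_fano_matches_pmf(self):
        for G in (1, 2, 3, 5, 6):
            for x in (0.5, 2.0, 10.0, 40.0):
                d = delay_distribution(G, x, 1.0)
                assert delay_fano(G, x) == pytest.approx(d.fano(), abs=1e-8)

    def test_monotone_decreasing_in_retention_time(self):
        xs = np.linspace(0.1, 50.0, 120)
        for G in (2, 3, 5, 6):
            ff = [delay_fano(G, x) for x in xs]
            assert np.all(np.diff(ff) < 0)

    def test_bounds(self):
        for G in (2, 3, 5):
            for x in (0.1, 1.0, 10.0, 100.0):
                assert 1.0 / G < delay_fano(G, x) < 1.0

    def test_compartment_comparison(self):
        # longer processing time => smaller Fano factor, for both compartments
        for G in (2, 3, 5):
            for tn, tc in ((0.5, 2.0), (1.0, 5.0), (3.0, 8.0)):
                assert delay_fano(G, tn) > delay_fano(G, tc)

    def test_cv_poisson_case_and_identity(self):
        assert delay_cv(1, 4.0, 1.0) == pytest.approx(0.5)
        for G, k, T in ((3, 10.0, 1.0), (4, 2.0, 6.0)):
            cv = delay_cv(G, k, T)
            mean = k * T / G
            assert cv**2 * mean == pytest.approx(delay_fano(G, k * T), rel=1e-12)

    def test_cv_monotone_in_T(self):
        for G in (1, 3):
            Ts = np.linspace(0.2, 20.0, 50)
            cvs = [delay_cv(G, 5.0, T) for T in Ts]
            assert np.all(np.diff(cvs) < 0)
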