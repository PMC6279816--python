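"""Closed-form analytics against limits, series and independent quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from inertial_abp import (
    ModelParams,
    SimConfig,
    angular_mean,
    angular_pdf,
    angular_variance,
    angular_velocity_pdf,
    delay_function_analytic,
    delay_numbers,
    dl_asymptotic_large_J,
    dl_asymptotic_small_J,
    f_delay,
    linear_velocity_pdf,
    long_time_diffusion,
    match_qW,
    msd_conditional,
    msd_stationary,
    orientation_correlation,
    orientation_correlation_two_time,
    persistence_time,
    short_time_msd,
    simulate_ensemble,
    speed_pdf,
    velocity_autocorrelation,
    velocity_second_moment,
)
from inertial_abp.analytics import _g_scalar


def delay_by_quadrature(p, t):
    """Independent oracle for the delay function.

    Built directly from the stationary solution of the velocity equation:
    <R'(t).n(0)> convolves the orientation correlation with the exponential
    velocity-relaxation kernel from the past of n(0); <R'(0).n(t)> from the
    past of the velocity at 0.  Never touches the incomplete-gamma route.
    """
    tau = p.tau
    a, _ = quad(lambda u: math.exp(-(t - u) / tau) * _g_scalar(p, abs(u)), -np.inf, 0,
                epsabs=1e-14, epsrel=1e-10, limit=400)
    b, _ = quad(lambda u: math.exp(-(t - u) / tau) * _g_scalar(p, abs(u)), 0, t,
                epsabs=1e-14, epsrel=1e-10, limit=400)
    c, _ = quad(lambda u: math.exp(u / tau) * _g_scalar(p, t - u), -np.inf, 0,
                epsabs=1e-14, epsrel=1e-10, limit=400)
    return p.V_p / tau * (a + b - c)


class TestOrientationCorrelation:
    def test_unity_at_zero_lag(self, fig2):
        assert orientation_correlation(fig2, 0.0) == 1.0

    def test_pure_rotation_gives_cosine(self):
        p = ModelParams(tau=0.1, tau_r=0.2, D=0, D_r=0.0, V_p=0, omega=3.0)
        t = np.linspace(0, 2, 50)
        assert np.allclose(orientation_correlation(p, t), np.cos(3.0 * t), atol=1e-14)

    def test_overdamped_limit_is_exponential_cosine(self):
        p = ModelParams(tau=1e-7, tau_r=1e-7, D=0, D_r=2.0, V_p=0, omega=1.5)
        t = np.linspace(0.01, 2, 40)
        expected = np.cos(1.5 * t) * np.exp(-2.0 * t)
        assert np.allclose(orientation_correlation(p, t), expected, rtol=1e-5)


class TestTwoTimeCorrelation:
    def test_equal_times_give_unity(self, fig2):
        t = np.linspace(0, 3, 30)
        vals = orientation_correlation_two_time(fig2, t, t, phi_dot0=1.3)
        assert np.allclose(vals, 1.0, atol=1e-14)

    def test_overdamped_limit_depends_on_lag_only(self):
        p = ModelParams(tau=1e-6, tau_r=1e-6, D=0, D_r=1.2, V_p=0, omega=0.8)
        lag = 0.7
        v = orientation_correlation_two_time(p, 2.0 + lag, 2.0, phi_dot0=p.omega)
        assert v == pytest.approx(math.exp(-1.2 * lag) * math.cos(0.8 * lag), rel=1e-4)

    def test_late_times_reduce_to_stationary_correlation(self, fig2):
        t0 = 30.0 * fig2.tau_r
        lags = np.array([0.05, 0.2, 0.5])
        two = orientation_correlation_two_time(fig2, t0 + lags, t0, phi_dot0=fig2.omega)
        assert np.allclose(two, orientation_correlation(fig2, lags), rtol=1e-10)


class TestFDelay:
    def test_zero_at_zero_d2(self):
        assert f_delay(0.48, 0.13, 0.0) == 0.0

    def test_approaches_one_for_large_d2(self):
        assert f_delay(0.48, 0.13, 1e4) == pytest.approx(1.0, abs=1e-2)
        assert f_delay(0.48, 0.13, 1e5) == pytest.approx(1.0, abs=1e-3)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        d0=st.floats(0.0, 10.0),
        d1=st.floats(-5.0, 5.0),
        d2=st.floats(0.0, 10.0),
    )
    def test_confined_to_unit_interval(self, d0, d1, d2):
        val = f_delay(d0, d1, d2)
        assert -1e-12 <= val <= 1.0 + 1e-12

    def test_negative_delay_numbers_rejected(self):
        with pytest.raises(ValueError):
            f_delay(-0.1, 0.0, 1.0)


class TestVelocitySecondMoment:
    def test_passive_particle_equipartition(self):
        p = ModelParams(tau=0.3, tau_r=0.2, D=2e-4, D_r=1.0, V_p=0.0, omega=0.0)
        assert velocity_second_moment(p) == pytest.approx(2 * p.D / p.tau, rel=1e-14)

    def test_small_inertia_limit(self, fig2):
        # torque-free: <v^2> -> 2D/tau + V_p^2 / (1 + tau D_r)
        p = fig2.with_(omega=0.0)
        ps = p.with_(tau_r=p.tau_r * 1e-5)
        expected = 2 * p.D / p.tau + p.V_p**2 / (1.0 + p.tau * p.D_r)
        assert velocity_second_moment(ps) == pytest.approx(expected, rel=1e-4)

    def test_large_inertia_limit_sums_thermal_and_injected_energy(self, fig2):
        # torque-free: with circling the active share saturates below V_p^2
        p = fig2.with_(omega=0.0)
        ps = p.with_(tau_r=p.tau_r * 1e6)
        expected = 2 * p.D / p.tau + p.V_p**2
        assert velocity_second_moment(ps) == pytest.approx(expected, rel=1e-4)

    def test_short_time_msd_is_ballistic(self, fig2):
        t = np.array([1e-4, 1e-3])
        assert np.allclose(short_time_msd(fig2, t), velocity_second_moment(fig2) * t**2)


class TestLongTimeDiffusion:
    def test_overdamped_torque_free_persistence(self, fig6):
        ps = fig6.with_(tau_r=fig6.tau_r * 1e-6)
        assert persistence_time(ps) == pytest.approx(1.0 / fig6.D_r, rel=1e-5)
        assert long_time_diffusion(ps) == pytest.approx(
            fig6.D + fig6.V_p**2 / (2 * fig6.D_r), rel=1e-5
        )

    def test_small_inertia_slope_matches_linear_term(self, fig6):
        h = 1e-6
        sl = (
            long_time_diffusion(fig6.with_(tau_r=h))
            - long_time_diffusion(fig6.with_(tau_r=h / 2))
        ) / (h / 2)
        assert sl == pytest.approx(fig6.V_p**2 / 2.0, rel=1e-4)

    def test_small_inertia_truncation(self, fig6):
        ps = fig6.with_(tau_r=fig6.tau_r * 1e-3)
        assert long_time_diffusion(ps) == pytest.approx(dl_asymptotic_small_J(ps), rel=1e-6)

    def test_large_inertia_sqrt_growth(self, fig6):
        ps = fig6.with_(tau_r=1e3 / fig6.D_r)
        assert long_time_diffusion(ps) / dl_asymptotic_large_J(ps) == pytest.approx(1.0, abs=1e-2)

    def test_monotone_in_moment_of_inertia(self, fig6):
        taus = np.geomspace(1e-4, 1e2, 25)
        dls = [long_time_diffusion(fig6.with_(tau_r=tr)) for tr in taus]
        assert np.all(np.diff(dls) > 0)

    def test_infinite_persistence_signalled_not_crashed(self):
        p = ModelParams(tau=0.1, tau_r=0.1, D=1e-4, D_r=0.0, V_p=0.1, omega=0.0)
        assert math.isinf(persistence_time(p))
        assert math.isinf(long_time_diffusion(p))


class TestMsd:
    def test_passive_conditional_closed_form(self):
        p = ModelParams(tau=0.2, tau_r=0.3, D=5e-5, D_r=1.0, V_p=0.0, omega=0.0)
        t = np.array([0.01, 0.1, 1.0, 5.0])
        e = np.exp(-t / p.tau)
        expected = 4 * p.D * t + 4 * p.D * p.tau * (e - 1 - 0.5 * (e - 1) ** 2)
        assert np.allclose(msd_conditional(p, t), expected, rtol=1e-12)

    def test_stationary_short_time_is_ballistic_with_v2(self, fig2):
        t = 1e-4
        ratio = msd_stationary(fig2, [t])[0] / t**2
        assert ratio == pytest.approx(velocity_second_moment(fig2), rel=1e-3)

    def test_stationary_long_time_slope_is_4DL(self, fig2):
        scale = max(fig2.tau, fig2.tau_r, 1 / fig2.D_r)
        T = 1e3 * scale
        m = msd_stationary(fig2, [T, 1.1 * T])
        slope = (m[1] - m[0]) / (0.1 * T) / 4.0
        assert slope == pytest.approx(long_time_diffusion(fig2), rel=1e-6)

    def test_conditional_long_time_slope_is_4DL(self, fig2):
        m = msd_conditional(fig2, [5.0, 6.0], R0_dot=(fig2.V_p, 0.0), phi_dot0=fig2.omega)
        slope = (m[1] - m[0]) / 4.0
        assert slope == pytest.approx(long_time_diffusion(fig2), rel=1e-4)

    def test_vacf_at_zero_equals_velocity_second_moment(self, fig2):
        assert velocity_autocorrelation(fig2, 0.0) == pytest.approx(
            velocity_second_moment(fig2), rel=1e-8
        )

    def test_overdamped_limit_matches_active_brownian_form(self):
        # tau, tau_r -> 0: MSD -> 4Dt + (2 V_p^2/D_r^2)(D_r t - 1 + e^(-D_r t))
        p = ModelParams(tau=2e-5, tau_r=2e-5, D=1e-4, D_r=1.0, V_p=0.1, omega=0.0)
        t = np.array([0.1, 0.5, 2.0, 10.0])
        expected = 4 * p.D * t + 2 * p.V_p**2 / p.D_r**2 * (p.D_r * t - 1 + np.exp(-p.D_r * t))
        assert np.allclose(msd_stationary(p, t), expected, rtol=2e-4)


class TestDelayFunction:
    def test_zero_at_time_zero(self, fig2):
        assert delay_function_analytic(fig2, [0.0])[0] == 0.0

    @pytest.mark.parametrize("preset_name", ["fig2", "fig6", "circle"])
    def test_matches_quadrature_oracle(self, preset_name, fig2, fig6):
        p = {"fig2": fig2, "fig6": fig6, "circle": fig2.with_(D_r=0.0)}[preset_name]
        ts = [0.03, 0.15, 0.4, 1.0]
        ana = delay_function_analytic(p, ts)
        ref = [delay_by_quadrature(p, t) for t in ts]
        assert np.allclose(ana, ref, rtol=1e-8, atol=1e-14)

    def test_overdamped_vanishes_for_all_times(self, fig2):
        ov = fig2.with_(tau=fig2.tau * 1e-4, tau_r=fig2.tau_r * 1e-4)
        peak = np.abs(delay_function_analytic(fig2, np.linspace(0, 2, 200))).max()
        ov_max = np.abs(delay_function_analytic(ov, np.linspace(0, 2, 200))).max()
        assert ov_max <= 1e-3 * peak

    def test_peak_location_regression(self, fig2):
        # dense-evaluation regression value for the generic-particle set
        t = np.linspace(0, 2, 4001)
        c = delay_function_analytic(fig2, t)
        assert t[np.argmax(c)] == pytest.approx(0.343, abs=5e-3)


class TestAngularLaws:
    def test_mean_angle_drift(self, fig2):
        t = 0.4
        expected = fig2.omega * t + (1.5 - fig2.omega) * fig2.tau_r * (
            1 - math.exp(-t / fig2.tau_r)
        )
        assert angular_mean(fig2, t, phi0=0.0, phi_dot0=1.5) == pytest.approx(expected)

    def test_variance_overdamped_limit(self):
        p = ModelParams(tau=0.1, tau_r=1e-8, D=0, D_r=1.7, V_p=0, omega=0)
        assert angular_variance(p, 0.5) == pytest.approx(2 * 1.7 * 0.5, rel=1e-6)

    def test_variance_short_time_cubic_coefficient(self, fig2):
        # numeric Taylor oracle: mu(t) = (2 D_r / 3 tau_r^2) t^3 + O(t^4)
        coeff = 2 * fig2.D_r / (3 * fig2.tau_r**2)
        for t in (1e-4, 1e-5):
            assert angular_variance(fig2, t) / t**3 == pytest.approx(coeff, rel=2e-3)

    def test_angular_pdf_normalised(self, fig2):
        phi = np.linspace(-20, 20, 4001)
        pdf = angular_pdf(fig2, 0.5, phi)
        assert np.trapezoid(pdf, phi) == pytest.approx(1.0, abs=1e-3)

    def test_angular_velocity_pdf_moments(self, fig2):
        w = np.linspace(fig2.omega - 30, fig2.omega + 30, 6001)
        pdf = angular_velocity_pdf(fig2, w)
        assert np.trapezoid(pdf, w) == pytest.approx(1.0, abs=1e-3)
        assert np.trapezoid(w * pdf, w) == pytest.approx(fig2.omega, abs=1e-6)
        var = np.trapezoid((w - fig2.omega) ** 2 * pdf, w)
        assert var == pytest.approx(fig2.D_r / fig2.tau_r, rel=1e-6)


class TestVelocityDistributions:
    def test_zero_propulsion_is_gaussian(self):
        v = np.linspace(-1, 1, 501)
        pdf = linear_velocity_pdf(0.01, 0.0, v)
        expected = np.exp(-(v**2) / 0.02) / math.sqrt(2 * math.pi * 0.01)
        assert np.allclose(pdf, expected, rtol=1e-10)

    def test_small_q_concentrates_on_cosine_support(self):
        W, q = 0.1, 1e-6
        v = np.linspace(-0.3, 0.3, 1201)
        pdf = linear_velocity_pdf(q, W, v)
        # all mass within the cosine support plus the Gaussian smoothing width
        inside = np.abs(v) <= W + 5 * math.sqrt(q)
        assert np.trapezoid(pdf[inside], v[inside]) >= 0.99
        # arcsine shape: denser near the edges than in the middle
        assert pdf[np.argmin(np.abs(v - 0.095))] > pdf[np.argmin(np.abs(v))]

    @pytest.mark.parametrize("q,W", [(0.01, 0.0), (0.0005, 0.09), (0.002, 0.05)])
    def test_pdfs_normalised(self, q, W):
        v = np.linspace(-(W + 8 * math.sqrt(q)), W + 8 * math.sqrt(q), 3001)
        assert np.trapezoid(linear_velocity_pdf(q, W, v), v) == pytest.approx(1.0, abs=1e-3)
        u = np.linspace(0, W + 10 * math.sqrt(q), 3001)
        assert np.trapezoid(speed_pdf(q, W, u), u) == pytest.approx(1.0, abs=1e-3)

    def test_speed_pdf_reduces_to_rayleigh_without_propulsion(self):
        q = 0.003
        v = np.linspace(0, 0.6, 400)
        expected = v / q * np.exp(-(v**2) / (2 * q))
        assert np.allclose(speed_pdf(q, 0.0, v), expected, rtol=1e-12)

    def test_matched_mixture_reproduces_simulated_histogram(self, fig2):
        q, W = match_qW(fig2)
        assert W**2 > q  # the activity-induced double peak regime
        cfg = SimConfig(dt=fig2.tau / 20, n_steps=4000, n_runs=96, seed=21,
                        init_mode="stationary", store_velocities=True)
        ens = simulate_ensemble(fig2, cfg)
        samples = np.concatenate([ens.vx.ravel(), ens.vy.ravel()])
        edges = np.linspace(samples.min(), samples.max(), 120)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        tv = 0.5 * np.sum(np.abs(linear_velocity_pdf(q, W, centers) - hist)) * (
            edges[1] - edges[0]
        )
        assert tv < 0.02

    def test_match_qW_consistent_with_second_moment(self, fig2):
        q, W = match_qW(fig2)
        assert q + 0.5 * W**2 == pytest.approx(0.5 * velocity_second_moment(fig2), rel=1e-12)
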