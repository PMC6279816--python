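"""Empirical estimators: exact small cases, invariances, I/O, convergence."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from inertial_abp import (
    Ensemble,
    ModelParams,
    SimConfig,
    Trajectory,
    add_tracking_noise,
    compute_curveset,
    delay_function_analytic,
    delay_function_empirical,
    empirical_distributions,
    empirical_msd,
    finite_difference_angular_velocity,
    finite_difference_velocity,
    read_trajectories,
    simulate_ensemble,
    write_trajectories,
)


def _line(times, vx=0.3, vy=0.0):
    return Trajectory(
        params=None,
        times=times,
        x=vx * times,
        y=vy * times,
        phi=np.zeros_like(times),
    )


class TestFiniteDifferences:
    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_uniform_motion_gives_constant_velocity(self, k):
        tr = _line(np.arange(50) * 0.1)
        vx, vy = finite_difference_velocity(tr, k)
        assert np.allclose(vx, 0.3) and np.allclose(vy, 0.0)
        assert vx.shape == (1, 50 - k)

    def test_two_point_trajectory_yields_single_sample(self):
        tr = _line(np.array([0.0, 0.5]))
        vx, _ = finite_difference_velocity(tr, 1)
        assert vx.shape == (1, 1)

    def test_too_short_trajectory_rejected(self):
        tr = _line(np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="short"):
            finite_difference_velocity(tr, 2)

    def test_angular_velocity_of_steady_spin(self):
        t = np.arange(30) * 0.05
        tr = Trajectory(params=None, times=t, x=0 * t, y=0 * t, phi=1.7 * t)
        w = finite_difference_angular_velocity(tr, 3)
        assert np.allclose(w, 1.7)


class TestEmpiricalMsd:
    def test_ballistic_trajectory_is_exact(self):
        tr = _line(np.arange(200) * 0.05, vx=0.2, vy=-0.1)
        c = empirical_msd(tr, lags=[1, 7, 50])
        assert np.allclose(c.y, (0.2**2 + 0.1**2) * c.x**2, rtol=1e-12)

    def test_lag_grid_and_band_shapes(self, fig2_ensemble):
        c = empirical_msd(fig2_ensemble, lags=[0, 1, 10, 100])
        assert len(c.x) == 3  # lag 0 (identically zero) is dropped from the grid
        assert np.all(c.sem >= 0)

    def test_invariant_under_global_rotation_and_translation(self, fig2_ensemble):
        ref = empirical_msd(fig2_ensemble, lags=[2, 20, 200]).y
        a = 0.77
        rot = Ensemble(
            params=fig2_ensemble.params,
            times=fig2_ensemble.times,
            x=1.5 + math.cos(a) * fig2_ensemble.x - math.sin(a) * fig2_ensemble.y,
            y=-0.3 + math.sin(a) * fig2_ensemble.x + math.cos(a) * fig2_ensemble.y,
            phi=fig2_ensemble.phi + a,
        )
        assert np.allclose(empirical_msd(rot, lags=[2, 20, 200]).y, ref, rtol=1e-12)

    def test_out_of_range_lag_rejected(self, fig2_ensemble):
        with pytest.raises(ValueError):
            empirical_msd(fig2_ensemble, lags=[10**6])

    def test_passive_long_lag_recovers_input_diffusivity(self):
        p = ModelParams(tau=0.05, tau_r=0.05, D=1e-4, D_r=1.0, V_p=0.0, omega=0.0)
        cfg = SimConfig(dt=5e-3, n_steps=4000, n_runs=48, seed=101, init_mode="stationary")
        ens = simulate_ensemble(p, cfg)
        c = empirical_msd(ens, lags=[800, 1200, 2000])
        d_est = c.y / (4 * c.x)
        d_sem = c.sem / (4 * c.x)
        z = np.abs(d_est - p.D) / d_sem
        assert z.max() < 3.0


class TestDistributions:
    def test_random_rotation_preserves_isotropic_statistics(self):
        rng = np.random.default_rng(0)
        t = np.arange(2001) * 0.01
        # isotropic Gaussian random walk: velocities are rotation invariant
        x = np.cumsum(rng.normal(0, 1e-3, (16, len(t))), axis=1)
        y = np.cumsum(rng.normal(0, 1e-3, (16, len(t))), axis=1)
        ens = Ensemble(params=None, times=t, x=x, y=y, phi=np.zeros_like(x))
        edges = np.linspace(-0.5, 0.5, 31)
        a = empirical_distributions(ens, k=1, bins=edges, rotation_seed=1)
        b = empirical_distributions(ens, k=1, bins=edges, rotation_seed=2)
        # same bin grid: pointwise agreement within a few s.e.m.
        pa, pb = a["pdf_linear_velocity"], b["pdf_linear_velocity"]
        sem = np.hypot(pa.sem, pb.sem)
        ok = sem > 0
        z = np.abs(pa.y - pb.y)[ok] / sem[ok]
        assert z.max() < 6.0
        assert abs(np.trapezoid(pa.y, pa.x) - 1.0) < 0.02

    def test_angular_velocity_histogram_is_shifted_gaussian(self, fig2_ensemble, fig2):
        d = empirical_distributions(fig2_ensemble, k=1)
        c = d["pdf_angular_velocity"]
        mean = np.trapezoid(c.x * c.y, c.x) / np.trapezoid(c.y, c.x)
        # mean equals omega within a few percent of the distribution width
        width = math.sqrt(fig2.D_r / fig2.tau_r)
        assert abs(mean - fig2.omega) < 0.05 * width
        ks = kstest(
            (np.concatenate([finite_difference_angular_velocity(fig2_ensemble, 1).ravel()])
             - mean),
            "norm",
            args=(0, np.concatenate(
                [finite_difference_angular_velocity(fig2_ensemble, 1).ravel()]).std()),
        )
        assert ks.statistic < 0.01  # visually Gaussian at this sample size

    def test_active_speed_law_departs_from_maxwell_boltzmann(self, fig2, fig2_ensemble):
        # passive twin with the same thermal scales
        passive = fig2.with_(V_p=0.0)
        cfg = SimConfig(dt=0.0066, n_steps=2000, n_runs=32, seed=55, init_mode="stationary")
        ens_p = simulate_ensemble(passive, cfg)

        def ks_vs_rayleigh(ens):
            vx, vy = finite_difference_velocity(ens, 1)
            spd = np.hypot(vx, vy).ravel()
            sigma = math.sqrt(0.5 * np.mean(spd**2))
            return kstest(spd, "rayleigh", args=(0, sigma)).statistic

        assert ks_vs_rayleigh(fig2_ensemble) > 3 * ks_vs_rayleigh(ens_p)

    def test_empty_ensemble_rejected(self):
        t = np.arange(3) * 0.1
        ens = Ensemble(params=None, times=t, x=np.zeros((1, 3)), y=np.zeros((1, 3)),
                       phi=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            empirical_distributions(ens, k=5)


class TestDelayFunctionEmpirical:
    def test_zero_lag_is_exactly_zero(self, fig2_ensemble):
        c = delay_function_empirical(fig2_ensemble, k=1, lags=[0, 1, 5])
        assert c.y[0] == 0.0

    def test_matches_analytic_curve_within_errors(self, fig2_ensemble, fig2):
        c = delay_function_empirical(fig2_ensemble, k=1, lags=np.arange(0, 150, 10))
        ana = delay_function_analytic(fig2, c.x)
        z = np.abs(c.y - ana) / np.where(c.sem > 0, c.sem, 1.0)
        assert z.max() < 3.5

    def test_invariant_under_global_rotation(self, fig2_ensemble):
        ref = delay_function_empirical(fig2_ensemble, k=1, lags=[3, 30]).y
        a = 1.1
        rot = Ensemble(
            params=fig2_ensemble.params,
            times=fig2_ensemble.times,
            x=math.cos(a) * fig2_ensemble.x - math.sin(a) * fig2_ensemble.y,
            y=math.sin(a) * fig2_ensemble.x + math.cos(a) * fig2_ensemble.y,
            phi=fig2_ensemble.phi + a,
        )
        assert np.allclose(delay_function_empirical(rot, k=1, lags=[3, 30]).y, ref, rtol=1e-10)

    def test_frame_multiple_choice_does_not_shift_the_curve(self, fig2_ensemble, fig2):
        # velocities over 1..4 frame intervals give consistent delay curves
        lag_times = None
        for k in (1, 2, 4):
            lags = np.arange(0, 120 // k, 10)
            c = delay_function_empirical(fig2_ensemble, k=k, lags=lags)
            ana = delay_function_analytic(fig2, c.x)
            z = np.abs(c.y - ana) / np.where(c.sem > 0, c.sem, 1.0)
            assert z.max() < 4.0


class TestTrackingNoise:
    def test_noise_inflates_short_lag_msd_only(self, fig2_ensemble):
        noisy = add_tracking_noise(fig2_ensemble, seed=4)
        c0 = empirical_msd(fig2_ensemble, lags=[1, 1000])
        c1 = empirical_msd(noisy, lags=[1, 1000])
        assert c1.y[0] > c0.y[0] + 1e-7  # ~ 2 sigma_xy^2 added at short lags
        assert c1.y[1] == pytest.approx(c0.y[1], rel=0.01)


class TestTrajectoryIO:
    def test_round_trip_is_exact(self, fig2_ensemble, tmp_path):
        f = tmp_path / "runs.csv"
        write_trajectories(fig2_ensemble, f)
        back = read_trajectories(f)
        assert np.array_equal(back.x, fig2_ensemble.x)
        assert np.array_equal(back.phi, fig2_ensemble.phi)
        assert back.run_ids == fig2_ensemble.run_ids

    def test_multi_run_grouping_preserved(self, tmp_path):
        t = np.arange(4) * 0.5
        ens = Ensemble(params=None, times=t, x=np.arange(8.0).reshape(2, 4),
                       y=np.zeros((2, 4)), phi=np.zeros((2, 4)), run_ids=[3, 7])
        f = tmp_path / "two.csv"
        write_trajectories(ens, f)
        back = read_trajectories(f)
        assert back.run_ids == [3, 7]
        assert np.array_equal(back.x, ens.x)

    def test_non_monotone_time_reports_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("t,x,y,phi\n0.0,0,0,0\n0.1,0,0,0\n0.05,0,0,0\n")
        with pytest.raises(ValueError, match="line 4"):
            read_trajectories(f)

    def test_missing_column_reported(self, tmp_path):
        f = tmp_path / "cols.csv"
        f.write_text("t,x,y\n0.0,0,0\n0.1,0,0\n")
        with pytest.raises(ValueError, match="phi"):
            read_trajectories(f)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        f = tmp_path / "nan.csv"
        f.write_text("t,x,y,phi\n0.0,0,0,0\n0.1,oops,0,0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_trajectories(f)


class TestCurveSet:
    def test_directory_round_trip(self, fig2_curves, tmp_path):
        d = tmp_path / "curves"
        fig2_curves.to_dir(d)
        back = type(fig2_curves).from_dir(d)
        assert back.v2_mean == pytest.approx(fig2_curves.v2_mean, rel=1e-10)
        assert np.allclose(back.msd_trans.y, fig2_curves.msd_trans.y, rtol=1e-10)
        assert np.allclose(back.delay_curve.sem, fig2_curves.delay_curve.sem, rtol=1e-6)
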