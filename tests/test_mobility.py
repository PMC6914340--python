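"""Tests of MSD estimation, the step-length mixture EM, immobile
detection and bleaching-step counting."""

import numpy as np
import pytest

from smcotrack import SimulationConfig, TrackSet, Trajectory, compute_msd, \
    count_bleach_steps, find_immobile, fit_diffusion_constant, \
    fit_step_length_mixture, simulate_membrane
from smcotrack.mobility import MSDCurve, StepLengthMixture, \
    UnidentifiableMixtureWarning

from conftest import sample_rayleigh_steps

DT = 0.032


def track_from_xy(xy, frames=None, track_id=0):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(track_id, "A", frames, xy, np.ones(len(xy)))


def brownian_tracks(rng, n_tracks, n_frames, d_um2_s, sigma_nm=0.0):
    sd = np.sqrt(2.0 * d_um2_s * 1e6 * DT)
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0, sd, (n_frames - 1, 2))
        xy = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
        if sigma_nm > 0:
            xy = xy + rng.normal(0, sigma_nm, xy.shape)
        tracks.append(track_from_xy(xy, track_id=i))
    return TrackSet(tracks, "A")


class TestMSD:
    def test_stationary_track_zero_msd(self):
        t = track_from_xy(np.tile([100.0, 200.0], (20, 1)))
        msd = compute_msd(t, max_lag=5, frame_time_s=DT)
        np.testing.assert_allclose(msd.msd_nm2, 0.0)

    def test_ballistic_track_quadratic_msd(self):
        d = 40.0
        t = track_from_xy([[d * f, 0.0] for f in range(30)])
        msd = compute_msd(t, max_lag=6, frame_time_s=DT)
        np.testing.assert_allclose(msd.msd_nm2,
                                   (d * np.arange(1, 7)) ** 2, rtol=1e-12)

    def test_brownian_msd_matches_closed_form(self):
        rng = np.random.default_rng(0)
        tracks = brownian_tracks(rng, 100, 102, 0.1)  # ~1e4 steps
        msd = compute_msd(tracks, max_lag=5, frame_time_s=DT)
        expected = 4.0 * 0.1 * 1e6 * msd.lag_s
        np.testing.assert_allclose(msd.msd_nm2, expected, rtol=0.05)

    def test_gap_spanning_lags_excluded(self):
        # frames 0,1,2,4: lag-2 pair (2,4) spans the missing frame 3
        t = track_from_xy([[0, 0], [10, 0], [20, 0], [40, 0]],
                          frames=[0, 1, 2, 4])
        msd = compute_msd(t, max_lag=2, frame_time_s=DT)
        assert msd.counts[0] == 2          # (0,1), (1,2)
        assert msd.counts[1] == 1          # (0,2) only
        assert msd.msd_nm2[1] == pytest.approx(400.0)

    def test_invalid_max_lag(self):
        with pytest.raises(ValueError):
            compute_msd(track_from_xy([[0, 0], [1, 1], [2, 2]]), max_lag=0)


class TestDiffusionFit:
    def make_exact_curve(self, d_um2_s, intercept=0.0):
        lags = np.arange(1, 11) * DT
        return MSDCurve(lags, 4 * d_um2_s * 1e6 * lags + intercept,
                        np.full(10, 100), DT)

    def test_exact_line_recovers_d(self):
        est = fit_diffusion_constant(self.make_exact_curve(0.1))
        assert est.d_um2_s == pytest.approx(0.1, rel=1e-9)
        assert est.intercept_nm2 == pytest.approx(0.0, abs=1e-6)

    def test_localization_error_goes_to_intercept(self):
        sigma = 30.0
        est = fit_diffusion_constant(self.make_exact_curve(0.1,
                                                           4 * sigma**2))
        assert est.d_um2_s == pytest.approx(0.1, rel=1e-9)
        assert est.intercept_nm2 == pytest.approx(3600.0, rel=1e-9)

    def test_ensemble_recovery_500_tracks(self):
        rng = np.random.default_rng(1)
        tracks = brownian_tracks(rng, 500, 150, 0.1)
        msd = compute_msd(tracks, max_lag=10, frame_time_s=DT)
        est = fit_diffusion_constant(msd, (2, 10))
        assert est.d_um2_s == pytest.approx(0.1, rel=0.1)

    def test_negative_slope_flagged_not_clipped_silently(self):
        lags = np.arange(1, 11) * DT
        curve = MSDCurve(lags, 1000.0 - 100.0 * np.arange(1, 11),
                         np.full(10, 50), DT)
        est = fit_diffusion_constant(curve)
        assert est.negative_slope
        assert est.d_um2_s == 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        tracks = brownian_tracks(rng, 50, 100, 0.08)
        est0 = fit_diffusion_constant(compute_msd(tracks, 10, DT))
        th = np.deg2rad(35.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = TrackSet([track_from_xy(t.xy_nm @ rot.T + [5e4, -2e3],
                                        t.frames, t.track_id)
                          for t in tracks], "A")
        est1 = fit_diffusion_constant(compute_msd(moved, 10, DT))
        assert est1.d_um2_s == pytest.approx(est0.d_um2_s, rel=1e-9)

    def test_too_few_lags_in_range(self):
        lags = np.arange(1, 3) * DT
        curve = MSDCurve(lags, 4e5 * lags, np.array([10, 10]), DT)
        with pytest.raises(ValueError):
            fit_diffusion_constant(curve, (2, 10))


class TestStepLengthMixture:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(3)
        steps = sample_rayleigh_steps(rng, 0.1, DT, 10_000)
        fit = fit_step_length_mixture(steps, DT, n_components=1)
        assert fit.alpha == 1.0
        assert fit.d1_um2_s == pytest.approx(0.1, rel=0.05)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(4)
        n = 10_000
        n_fast = int(0.7 * n)
        steps = np.concatenate([
            sample_rayleigh_steps(rng, 0.15, DT, n_fast),
            sample_rayleigh_steps(rng, 0.02, DT, n - n_fast)])
        fit = fit_step_length_mixture(steps, DT, seed=0)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.7, abs=0.1)
        assert fit.d1_um2_s == pytest.approx(0.15, rel=0.2)
        assert fit.d2_um2_s == pytest.approx(0.02, rel=0.2)

    def test_loglik_monotone_across_iterations(self):
        rng = np.random.default_rng(5)
        steps = np.concatenate([sample_rayleigh_steps(rng, 0.2, DT, 3000),
                                sample_rayleigh_steps(rng, 0.03, DT, 3000)])
        fit = fit_step_length_mixture(steps, DT, seed=1)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-6 * np.abs(fit.loglik_path[:-1])).all()

    def test_equal_components_warn_unidentifiable(self):
        rng = np.random.default_rng(6)
        steps = sample_rayleigh_steps(rng, 0.1, DT, 5000)
        with pytest.warns(UnidentifiableMixtureWarning):
            fit = fit_step_length_mixture(steps, DT, seed=2)
        assert not fit.identifiable

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            StepLengthMixture(np.array([1.0, -2.0]), DT)
        with pytest.raises(ValueError):
            StepLengthMixture(np.array([1.0, 2.0]), 0.0)
        with pytest.warns(UserWarning, match="fewer than 50"):
            StepLengthMixture(np.full(10, 5.0), DT)

    def test_slow_fraction_tracks_dimer_fraction(self):
        """More dimers (slower species) -> larger slow mixture fraction."""
        from smcotrack import LinkingParams, link_localizations, \
            render_localizations
        from smcotrack.mobility import collect_step_lengths
        alphas = []
        for frac in (0.1, 0.8):
            cfg = SimulationConfig(n_receptors=300, dimer_fraction=frac,
                                   d_monomer=0.15, d_dimer=0.02,
                                   roi_width_um=30.0, roi_height_um=30.0,
                                   sigma_loc_nm=0.0, seed=30)
            truth = simulate_membrane(cfg)
            ta, tb = render_localizations(truth, cfg)
            steps = []
            for tab in (ta, tb):
                steps.append(collect_step_lengths(
                    link_localizations(tab, LinkingParams())))
            fit = fit_step_length_mixture(np.concatenate(steps), DT, seed=3)
            alphas.append(1.0 - fit.alpha)     # slow fraction
        assert alphas[1] > alphas[0] + 0.2


class TestFindImmobile:
    def test_jittering_track_is_immobile(self):
        rng = np.random.default_rng(7)
        xy = np.array([500.0, 500.0]) + rng.normal(0, 8.0, (100, 2))
        flags = find_immobile(TrackSet([track_from_xy(xy)], "A"), eps_nm=50)
        assert flags.tolist() == [True]

    def test_fast_brownian_track_is_mobile(self):
        rng = np.random.default_rng(8)
        tracks = brownian_tracks(rng, 5, 150, 0.1)
        flags = find_immobile(tracks, eps_nm=50)
        assert not flags.any()

    def test_empty_trackset(self):
        assert find_immobile(TrackSet([], "A"), eps_nm=50).size == 0

    def test_mixed_population_separated(self):
        rng = np.random.default_rng(9)
        mobile = brownian_tracks(rng, 3, 120, 0.1)
        stuck = [track_from_xy(np.array([9e4, 9e4])
                               + rng.normal(0, 10.0, (120, 2)), track_id=10)]
        flags = find_immobile(TrackSet(mobile.tracks + stuck, "A"), eps_nm=50)
        assert flags.tolist() == [False, False, False, True]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_immobile(TrackSet([], "A"), eps_nm=0)
        with pytest.raises(ValueError):
            find_immobile(TrackSet([], "A"), eps_nm=10, min_pts=1)


class TestBleachSteps:
    def test_noiseless_two_step_trace(self):
        trace = np.concatenate([np.full(40, 2.0), np.full(30, 1.0),
                                np.zeros(50)])
        res = count_bleach_steps(trace)
        assert res.n_steps == 2
        assert res.change_points == [40, 70]
        assert res.segment_means == pytest.approx([2.0, 1.0, 0.0])

    def test_constant_trace_zero_steps(self):
        assert count_bleach_steps(np.full(80, 3.0)).n_steps == 0

    def test_single_step_snr5_detection_rate(self):
        # unit step at a known change point, noise SD 0.2 (SNR 5)
        correct = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            trace = np.concatenate([np.ones(70), np.zeros(80)])
            trace = trace + rng.normal(0, 0.2, 150)
            if count_bleach_steps(trace).n_steps == 1:
                correct += 1
        assert correct >= 0.95 * 200

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            count_bleach_steps(np.full(20, np.nan))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            count_bleach_steps(np.array([1.0, 0.0]))
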