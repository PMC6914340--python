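"""Tests of the membrane monomer-dimer simulator and renderers."""

import numpy as np
import pytest

from smcotrack import SimulationConfig, simulate_membrane, \
    render_localizations, simulate_fiducial_beads, simulate_intensity_trace, \
    make_affinity_series, fit_affine
from smcotrack.synthetic import ConfigurationError

from conftest import mean_field_dimer_fraction


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"dimer_fraction": 1.5},
        {"p_label_a": 0.7, "p_label_b": 0.7},
        {"d_monomer": -0.1},
        {"mode": "kinetic"},                          # missing rates
        {"k_on_2d": 0.1},                             # kinetic param in static
        {"k_off": 1.0},
        {"mode": "nonsense"},
        {"detection_eff": 1.5},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kw)

    def test_acquisition_defaults(self):
        cfg = SimulationConfig()
        assert cfg.frame_time_s == 0.032
        assert cfg.n_frames == 150


class TestSimulateMembrane:
    def test_no_dimers_requested_gives_none(self, small_config):
        truth = simulate_membrane(small_config)
        assert (truth.partner == -1).all()

    def test_kinetic_zero_on_rate_stays_monomeric(self):
        cfg = SimulationConfig(mode="kinetic", k_on_2d=0.0, k_off=1.0,
                               n_receptors=50, n_frames=60, seed=1)
        truth = simulate_membrane(cfg)
        assert (truth.partner == -1).all()

    def test_partner_relation_symmetric_irreflexive(self):
        cfg = SimulationConfig(n_receptors=40, dimer_fraction=0.5,
                               n_frames=30, seed=2)
        truth = simulate_membrane(cfg)
        for f in range(truth.n_frames):
            p = truth.partner[f]
            paired = np.flatnonzero(p >= 0)
            assert not (p[paired] == paired).any()
            assert (p[p[paired]] == paired).all()

    def test_static_mode_hits_requested_fraction(self):
        cfg = SimulationConfig(n_receptors=200, dimer_fraction=0.4, seed=3)
        truth = simulate_membrane(cfg)
        assert truth.dimer_fraction_per_frame() == pytest.approx(0.4)

    def test_positions_stay_inside_roi(self):
        cfg = SimulationConfig(n_receptors=50, n_frames=200, d_monomer=0.5,
                               roi_width_um=2.0, roi_height_um=2.0, seed=4)
        truth = simulate_membrane(cfg)
        assert truth.positions_nm[:, :, 0].min() >= 0
        assert truth.positions_nm[:, :, 0].max() <= 2000
        assert truth.positions_nm[:, :, 1].max() <= 2000

    def test_dimer_partners_colocated_every_frame(self):
        cfg = SimulationConfig(n_receptors=60, dimer_fraction=1.0,
                               n_frames=50, seed=5)
        truth = simulate_membrane(cfg)
        for f in range(truth.n_frames):
            p = truth.partner[f]
            paired = np.flatnonzero(p >= 0)
            np.testing.assert_array_equal(truth.positions_nm[f, paired],
                                          truth.positions_nm[f, p[paired]])

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_receptors=30, dimer_fraction=0.3, seed=11)
        a = simulate_membrane(cfg)
        b = simulate_membrane(cfg)
        np.testing.assert_array_equal(a.positions_nm, b.positions_nm)
        c = simulate_membrane(SimulationConfig(n_receptors=30,
                                               dimer_fraction=0.3, seed=12))
        assert not np.array_equal(a.positions_nm, c.positions_nm)

    def test_monomer_ensemble_msd_matches_brownian_limit(self):
        # >= 1e4 steps; periodic boundary keeps raw displacements Brownian
        cfg = SimulationConfig(n_receptors=150, n_frames=101, d_monomer=0.1,
                               roi_width_um=200.0, roi_height_um=200.0,
                               seed=6)
        truth = simulate_membrane(cfg)
        disp = np.diff(truth.positions_nm, axis=0)
        msd1 = float((disp**2).sum(axis=-1).mean())
        expected = 4.0 * 0.1 * 1e6 * 0.032
        assert msd1 == pytest.approx(expected, rel=0.05)

    def test_kinetic_fixed_point_matches_mean_field_recursion(self):
        cfg = SimulationConfig(mode="kinetic", k_on_2d=0.1, k_off=0.5,
                               n_receptors=200, n_frames=1200, seed=3)
        truth = simulate_membrane(cfg)
        sim = float(truth.dimer_fraction_per_frame()[400:].mean())
        oracle = mean_field_dimer_fraction(cfg)
        assert sim == pytest.approx(oracle, rel=0.25)

    def test_kinetic_pair_lifetime_near_inverse_koff(self):
        cfg = SimulationConfig(mode="kinetic", k_on_2d=0.2, k_off=0.5,
                               n_receptors=200, n_frames=1500, seed=9)
        truth = simulate_membrane(cfg)
        runs = []
        for i in range(cfg.n_receptors):
            bound = truth.partner[:, i] >= 0
            run = 0
            for flag in bound:
                if flag:
                    run += 1
                elif run:
                    runs.append(run)
                    run = 0
            # censored final runs dropped
        assert len(runs) > 50
        mean_life_s = np.mean(runs) * cfg.frame_time_s
        assert mean_life_s == pytest.approx(1.0 / cfg.k_off, rel=0.25)


class TestRenderLocalizations:
    def test_noiseless_single_species_reproduces_truth(self):
        cfg = SimulationConfig(n_receptors=25, n_frames=20, sigma_loc_nm=0.0,
                               p_label_a=1.0, p_label_b=0.0, seed=8)
        truth = simulate_membrane(cfg)
        ta, tb = render_localizations(truth, cfg)
        assert len(tb) == 0
        assert len(ta) == 25 * 20
        xy = ta.df.sort_values(["frame", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        true_xy = np.concatenate([
            truth.positions_nm[f][np.argsort(truth.positions_nm[f, :, 0])]
            for f in range(20)])
        np.testing.assert_allclose(xy, true_xy)

    def test_two_color_dimer_fraction_matches_binomial(self):
        cfg = SimulationConfig(n_receptors=4000, dimer_fraction=1.0,
                               n_frames=2, p_label_a=0.5, p_label_b=0.5,
                               seed=10)
        truth = simulate_membrane(cfg)
        render_localizations(truth, cfg)
        lab = truth.label_species
        p = truth.partner[0]
        leaders = np.flatnonzero((p >= 0) & (np.arange(len(p)) < p))
        two_color = np.mean((lab[leaders] != lab[p[leaders]])
                            & (lab[leaders] != "dark")
                            & (lab[p[leaders]] != "dark"))
        assert two_color == pytest.approx(2 * 0.5 * 0.5, abs=0.03)

    def test_detection_efficiency_is_binomial(self):
        cfg = SimulationConfig(n_receptors=10000, n_frames=3,
                               roi_width_um=100.0, roi_height_um=100.0,
                               p_label_a=1.0, p_label_b=0.0,
                               detection_eff=0.8, seed=12)
        truth = simulate_membrane(cfg)
        ta, _ = render_localizations(truth, cfg)
        per_frame = ta.df.groupby("frame").size().to_numpy()
        assert per_frame.mean() == pytest.approx(0.8 * 10000, rel=0.02)

    def test_bleaching_is_irreversible(self):
        cfg = SimulationConfig(n_receptors=300, n_frames=100, p_label_a=1.0,
                               p_label_b=0.0, bleach_rate=0.05, seed=13)
        truth = simulate_membrane(cfg)
        ta, _ = render_localizations(truth, cfg)
        # no localization at or after the recorded bleach frame
        counts = ta.df.groupby("frame").size()
        assert counts.iloc[-1] < counts.iloc[0]
        df = truth.to_dataframe()
        merged = ta.df.merge(df, left_on=["frame", "x_nm", "y_nm"],
                             right_on=["frame", "true_x_nm", "true_y_nm"])
        assert not merged["bleached"].any()


class TestFiducialsAndTraces:
    def test_identity_no_noise_identical_channels(self):
        a, b = simulate_fiducial_beads(10, None, 0.0, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_pure_translation(self):
        from smcotrack import AffineTransform2D
        t = AffineTransform2D(offset=(50.0, -20.0))
        a, b = simulate_fiducial_beads(8, t, 0.0, seed=2)
        np.testing.assert_allclose(b - a, np.tile([50.0, -20.0], (8, 1)))

    def test_rotation_shear_recoverable_to_noise_rms(self):
        from smcotrack import AffineTransform2D
        t = AffineTransform2D.from_params(rotation_deg=2.0, shear=0.01)
        a, b = simulate_fiducial_beads(200, t, 5.0, seed=3)
        fit = fit_affine(a, b)  # maps B back onto A
        assert fit.residual_rms_nm == pytest.approx(5.0, rel=0.3)

    def test_bead_count_validation(self):
        with pytest.raises(ValueError):
            simulate_fiducial_beads(0)

    def test_two_fluorophore_noiseless_trace_levels(self):
        trace = simulate_intensity_trace(2, 0.05, 0.0, 150, seed=4)
        assert set(np.unique(trace)) <= {0.0, 1.0, 2.0}
        assert (np.diff(trace) <= 0).all()
        assert (np.diff(trace) < 0).sum() == 2

    def test_zero_fluorophores_all_zero(self):
        assert not simulate_intensity_trace(0, 0.1, 0.0, 50, seed=5).any()

    def test_geometric_mean_bleach_time(self):
        times = [np.argmin(simulate_intensity_trace(1, 0.05, 0.0, 2000,
                                                    seed=s) > 0)
                 for s in range(500)]
        assert np.mean(times) == pytest.approx(20.0, rel=0.15)


class TestAffinitySeries:
    def test_construction_and_labels(self):
        base = SimulationConfig(n_receptors=20, n_frames=10)
        out = make_affinity_series(
            base, [0.0, 0.05, 0.15, 0.45, 0.5],
            labels=["unstim", "A1", "C7", "Mut3", "HyIL-6"])
        assert [s.label for s in out] == ["unstim", "A1", "C7", "Mut3",
                                         "HyIL-6"]
        assert [s.dimer_fraction for s in out] == [0.0, 0.05, 0.15, 0.45, 0.5]

    def test_empty_series(self):
        assert make_affinity_series(SimulationConfig(), []) == []

    def test_true_fractions_realized(self):
        base = SimulationConfig(n_receptors=100, n_frames=5)
        out = make_affinity_series(base, [0.0, 0.5], seed=3)
        for s in out:
            assert s.truth.dimer_fraction_per_frame()[0] == pytest.approx(
                s.dimer_fraction, abs=0.01)
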