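"""Generator correctness: closed-form statistics, degenerate cases and
bit-reproducibility of the synthetic-data module."""

import numpy as np
import pandas as pd
import pytest

from punctakit import simulate as sim


class TestTrajectories:
    def test_brownian_ensemble_msd_matches_4dt(self, brownian_tracks):
        obs, _, cfg = brownian_tracks
        for lag in (1, 3, 5):
            disp = obs[:, lag:, :] - obs[:, :-lag, :]
            msd = float((disp**2).sum(axis=-1).mean())
            expected = 4 * 0.0308 * lag * cfg.frame_interval_s
            assert abs(msd / expected - 1) < 0.05

    def test_all_immobile_zero_jitter_is_constant(self):
        cfg = sim.SceneConfig(
            n_puncta=5, n_frames=20, state_fractions={"immobile": 1.0}, seed=2
        )
        obs, _ = sim.simulate_trajectories(
            cfg, {"immobile": sim.MotionModel("immobile", jitter_sd=0.0)}
        )
        assert np.all(obs == obs[:, :1, :])

    def test_directed_net_displacement_is_vt(self):
        # 0.324 µm/s for 3 s -> 0.972 µm, exactly, without noise terms
        cfg = sim.SceneConfig(
            n_puncta=4,
            n_frames=31,
            state_fractions={"directed": 1.0},
            seed=3,
            field_size_um=(50.0, 50.0),
        )
        m = {"directed": sim.MotionModel("directed", v=0.324, D=0.0, jitter_sd=0.0)}
        obs, _ = sim.simulate_trajectories(cfg, m, margin_um=10)
        net = np.hypot(*(obs[:, 30] - obs[:, 0]).T)
        assert np.allclose(net, 0.972, atol=1e-9)

    def test_state_fractions_within_binomial_ci(self):
        cfg = sim.SceneConfig(n_puncta=2000, n_frames=2, seed=4, field_size_um=(300, 300))
        _, truth = sim.simulate_trajectories(cfg)
        for kind, p in sim.DEFAULT_STATE_FRACTIONS.items():
            k = (truth.puncta["kind"] == kind).sum()
            half = 2.58 * np.sqrt(p * (1 - p) / 2000)  # 99% CI
            assert abs(k / 2000 - p) < half + 1e-12

    def test_same_seed_bit_identical(self):
        cfg = sim.SceneConfig(n_puncta=10, n_frames=10, seed=7)
        a, _ = sim.simulate_trajectories(cfg)
        b, _ = sim.simulate_trajectories(cfg)
        assert np.array_equal(a, b)

    def test_coordinates_stay_inside_field(self):
        cfg = sim.SceneConfig(
            n_puncta=50,
            n_frames=200,
            seed=8,
            field_size_um=(5.0, 5.0),
            state_fractions={"directed": 1.0},
        )
        obs, truth = sim.simulate_trajectories(
            cfg, {"directed": sim.MotionModel("directed", v=0.324, D=0.01)}
        )
        assert truth.true_positions.min() >= 0
        assert truth.true_positions[..., 0].max() <= 5.0
        assert truth.true_positions[..., 1].max() <= 5.0

    def test_invalid_configuration_raises(self):
        with pytest.raises(sim.InvalidConfiguration):
            sim.SceneConfig(frame_interval_s=0.0)
        with pytest.raises(sim.InvalidConfiguration):
            sim.SceneConfig(state_fractions={"diffusive": 0.8})
        with pytest.raises(sim.InvalidConfiguration):
            sim.MotionModel("subdiffusive", D=0.01)
        cfg = sim.SceneConfig(n_puncta=3, n_frames=5)
        with pytest.raises(sim.InvalidConfiguration):
            sim.simulate_trajectories(cfg, models={})


class TestRenderMovie:
    def test_maximum_at_true_position(self):
        cfg = sim.SceneConfig(
            field_size_um=(4.8, 4.8), noise_sd=0.0, n_frames=1, seed=0
        )
        traj = np.array([[[1.60, 2.40]]])  # pixel (10, 15)
        movie = sim.render_movie(traj, cfg, intensities=300.0)
        y, x = np.unravel_index(np.argmax(movie.data[0]), movie.data[0].shape)
        assert (x, y) == (10, 15)

    def test_zero_puncta_pure_background(self):
        cfg = sim.SceneConfig(field_size_um=(3.2, 3.2), noise_sd=0.0, n_frames=3, seed=0)
        movie = sim.render_movie(np.empty((0, 3, 2)), cfg, intensities=np.empty(0))
        assert np.allclose(movie.data, cfg.background)

    def test_flux_proportional_to_fluorophore_count(self):
        # noise-free: summed intensity above background == planted intensity
        cfg = sim.SceneConfig(field_size_um=(9.6, 9.6), noise_sd=0.0, n_frames=1, seed=0)
        for count in (1, 8):
            traj = np.array([[[4.8, 4.8]]])
            movie = sim.render_movie(traj, cfg, intensities=100.0 * count)
            flux = float((movie.data[0] - cfg.background).sum())
            assert abs(flux - 100.0 * count) < 1e-3 * count  # float32 frames

    def test_out_of_field_clipped_with_warning(self):
        cfg = sim.SceneConfig(field_size_um=(3.2, 3.2), noise_sd=0.0, n_frames=1, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            sim.render_movie(np.array([[[10.0, 1.0]]]), cfg, intensities=100.0)


class TestBleachTrace:
    def test_noise_free_staircase_has_equal_unit_steps(self):
        t = sim.simulate_bleach_trace(
            5, unitary_intensity=100.0, bleach_rate=4.0, noise_sd=0.0,
            n_frames=300, seed=11,
        )
        drops = -np.diff(t.intensity)
        steps = drops[drops > 0]
        assert t.intensity[0] == 500.0
        assert np.allclose(steps[steps > 0] % 100.0, 0.0)
        assert t.intensity[-1] == 0.0

    def test_zero_fluorophores_flat(self):
        t = sim.simulate_bleach_trace(0, noise_sd=0.0, background=7.0, n_frames=50)
        assert np.allclose(t.intensity, 7.0)

    def test_initial_intensity_is_n_times_unitary(self):
        t = sim.simulate_bleach_trace(8, unitary_intensity=100.0, noise_sd=0.0, seed=2)
        assert t.intensity[0] == 800.0

    def test_expected_trace_monotone_nonincreasing(self):
        t = sim.simulate_bleach_trace(10, noise_sd=0.0, seed=5)
        assert np.all(np.diff(t.intensity) <= 0)


class TestFrapCurve:
    @staticmethod
    def _normalized(s):
        ratio = s.roi / s.cell
        return ratio / ratio[: s.bleach_frame].mean()

    def test_full_mobility_returns_to_prebleach(self):
        s = sim.simulate_frap_curve(mf=1.0, t_half_s=5.0, noise_sd=0.0, duration_s=500)
        f = self._normalized(s)
        assert abs(f[-1] - 1.0) < 1e-6

    def test_zero_mobility_flat_at_postbleach(self):
        s = sim.simulate_frap_curve(
            mf=0.0, t_half_s=62.0, bleach_depth=0.8, noise_sd=0.0
        )
        f = self._normalized(s)
        post = f[s.bleach_frame :]
        assert np.allclose(post, post[0])

    def test_half_recovery_identity_at_t_half(self):
        # at t = t_half the recovered fraction is exactly Mf/2
        s = sim.simulate_frap_curve(mf=0.77, t_half_s=62.0, noise_sd=0.0)
        f = self._normalized(s)
        i = int(np.argmin(np.abs(s.time_s - 62.0)))
        f_b = 1.0 - s.true_bleach_depth
        assert abs(f[i] - (f_b + 0.385 * (1.0 - f_b))) < 1e-9


class TestPuffScene:
    def _scene(self, **kw):
        cfg = sim.SceneConfig(
            field_size_um=(12.8, 12.8),
            frame_interval_s=0.05,
            n_frames=100,
            noise_sd=0.0,
            seed=1,
        )
        imm = np.array([[4.0, 4.0], [9.0, 9.0]])
        return sim.simulate_puff_scene(cfg, imm, **kw)

    def test_all_events_at_sites(self):
        _, truth = self._scene(
            p_site_active=1.0, p_puff_at_immobile=1.0, puff_rate=0.5, seed=2
        )
        ev = truth.puffs
        assert len(ev) > 0
        assert (ev["punctum_id"] >= 0).all()
        sites = np.array([[4.0, 4.0], [9.0, 9.0]])
        d = np.hypot(
            ev["x_um"].to_numpy() - sites[ev["punctum_id"], 0],
            ev["y_um"].to_numpy() - sites[ev["punctum_id"], 1],
        )
        assert np.allclose(d, 0.0)

    def test_zero_rate_no_events(self):
        _, truth = self._scene(puff_rate=0.0)
        assert len(truth.puffs) == 0

    def test_duration_spans_expected_frames(self):
        # 0.2 s at 0.05 s/frame -> 4 frames
        _, truth = self._scene(
            p_site_active=1.0, puff_rate=0.5, duration_s=0.2, seed=3
        )
        assert (truth.puffs["n_frames"] == 4).all()

    def test_no_immobile_with_positive_probability_raises(self):
        cfg = sim.SceneConfig(n_frames=10, seed=0)
        with pytest.raises(sim.InvalidConfiguration):
            sim.simulate_puff_scene(cfg, np.empty((0, 2)), p_puff_at_immobile=0.5)


class TestStim1Field:
    def test_empty_when_no_parents_and_no_background(self):
        imm = np.array([[5.0, 5.0]])
        pattern, _ = sim.simulate_stim1_field(
            imm, None, (10, 10), p_juxtaposed=0.0, background_density=0.0
        )
        assert len(pattern) == 0

    def test_exact_offset_when_sd_zero(self):
        rng = np.random.default_rng(0)
        imm = rng.uniform(2, 18, (40, 2))
        pattern, truth = sim.simulate_stim1_field(
            imm,
            None,
            (20, 20),
            p_juxtaposed=1.0,
            offset_mean_um=0.70,
            offset_sd_um=0.0,
            background_density=0.0,
            seed=5,
        )
        parents = truth.stim_points["parent_punctum"].to_numpy()
        d = np.hypot(*(pattern.points - imm[parents]).T)
        assert np.allclose(d, 0.70, atol=1e-9)

    def test_poisson_background_nn_distance_closed_form(self):
        # mean NN distance of a homogeneous Poisson process is 1/(2*sqrt(lambda))
        from punctakit.junctions import nn_distances

        pattern, _ = sim.simulate_stim1_field(
            np.empty((0, 2)),
            None,
            (120, 120),
            p_juxtaposed=0.0,
            background_density=1.0,
            seed=6,
        )
        d = nn_distances(pattern, pattern)
        assert abs(d.mean() - 0.5) < 0.025

    def test_reproducible(self):
        imm = np.array([[3.0, 3.0], [7.0, 7.0]])
        a, _ = sim.simulate_stim1_field(imm, None, (10, 10), seed=9)
        b, _ = sim.simulate_stim1_field(imm, None, (10, 10), seed=9)
        assert np.array_equal(a.points, b.points)


def test_ground_truth_maps_one_record_per_punctum():
    cfg = sim.SceneConfig(n_puncta=25, n_frames=5, seed=12)
    obs, truth = sim.simulate_trajectories(cfg)
    assert len(truth.puncta) == 25
    assert truth.true_positions.shape == (25, 5, 2)
    assert truth.puncta["punctum_id"].is_unique
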