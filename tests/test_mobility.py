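"""MSD computation, motion classification, overlay-based immobile
identification, directed speed and mobility summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctakit import simulate as sim
from punctakit.mobility import (
    ClassifierConfig,
    classify_trajectory,
    compute_msd,
    directed_speed,
    mobility_summary,
    overlay_immobile,
    split_by_motion_change,
)

DT = 0.1


def linear_track(v=0.324, n=40, heading=0.0):
    t = np.arange(n) * DT
    return np.column_stack(
        [5 + v * t * np.cos(heading), 5 + v * t * np.sin(heading)]
    )


class TestComputeMsd:
    def test_linear_motion_closed_form(self):
        prof = compute_msd(linear_track(), DT)
        assert prof.alpha == pytest.approx(2.0, abs=1e-6)
        assert prof.straightness == pytest.approx(1.0)
        assert np.allclose(prof.msd_um2, 0.324**2 * prof.lags_s**2)

    def test_stationary_track_flagged(self):
        pos = np.full((40, 2), 3.0)
        prof = compute_msd(pos, DT)
        assert np.all(prof.msd_um2 == 0)
        assert not prof.alpha_valid

    def test_short_track_raises_with_minimum_named(self):
        with pytest.raises(ValueError, match="30"):
            compute_msd(np.zeros((10, 2)), DT)

    def test_pooled_brownian_d_within_ten_percent(self, brownian_tracks):
        obs, _, cfg = brownian_tracks
        ds = [
            compute_msd(obs[i], cfg.frame_interval_s).D_um2_s
            for i in range(len(obs))
        ]
        assert abs(np.mean(ds) / 0.0308 - 1) < 0.10

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 0.08, (40, 2)), axis=0)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pos @ R.T + np.array([11.0, -4.0])
        p0, p1 = compute_msd(pos, DT), compute_msd(moved, DT)
        assert np.allclose(p0.msd_um2, p1.msd_um2, rtol=1e-9)
        assert p0.straightness == pytest.approx(p1.straightness)


class TestClassification:
    def test_jitter_only_track_is_immobile(self):
        rng = np.random.default_rng(0)
        pos = 5.0 + rng.normal(0, 0.01, (40, 2))
        assert classify_trajectory(compute_msd(pos, DT)) == "immobile"

    def test_straight_constant_velocity_is_directed(self):
        # per-frame displacement must clear the 40 nm mobility floor
        assert classify_trajectory(compute_msd(linear_track(v=0.6), DT)) == "directed"

    def test_confined_track_is_subdiffusive(self):
        cfg = sim.SceneConfig(
            n_puncta=30, n_frames=60, state_fractions={"subdiffusive": 1.0}, seed=5
        )
        m = {
            "subdiffusive": sim.MotionModel(
                "subdiffusive", D=0.0308, confinement_radius=0.15, jitter_sd=0.02
            )
        }
        obs, _ = sim.simulate_trajectories(cfg, m)
        labels = [
            classify_trajectory(compute_msd(obs[i], DT)) for i in range(len(obs))
        ]
        frac = labels.count("subdiffusive") / len(labels)
        assert frac >= 0.85

    @pytest.mark.parametrize("kind", ["immobile", "subdiffusive", "diffusive", "directed"])
    def test_pure_ensembles_thirty_frames_accuracy(self, kind):
        """Per-kind accuracy >= 85% on 30-frame tracks at default noise."""
        cfg = sim.SceneConfig(
            n_puncta=800,
            n_frames=30,
            state_fractions={kind: 1.0},
            seed=99,
            field_size_um=(300, 300),
        )
        m = sim.default_models()
        obs, _ = sim.simulate_trajectories(cfg, {kind: m[kind]}, margin_um=10)
        labels = [
            classify_trajectory(compute_msd(obs[i], DT, min_track_frames=30))
            for i in range(len(obs))
        ]
        assert labels.count(kind) / len(labels) >= 0.85

    def test_deterministic(self):
        prof = compute_msd(linear_track(), DT)
        assert classify_trajectory(prof) == classify_trajectory(prof)


class TestDirectedSpeed:
    def test_exact_on_noise_free_linear_track(self):
        v = directed_speed(linear_track(v=0.324), DT)
        assert v == pytest.approx(0.324, rel=1e-6)

    def test_brownian_track_speed_near_zero(self):
        cfg = sim.SceneConfig(
            n_puncta=100,
            n_frames=100,
            state_fractions={"diffusive": 1.0},
            seed=7,
            field_size_um=(200, 200),
        )
        m = {"diffusive": sim.MotionModel("diffusive", D=0.0308, jitter_sd=0.0)}
        obs, _ = sim.simulate_trajectories(cfg, m, margin_um=10)
        vs = np.array([directed_speed(obs[i], DT) for i in range(100)])
        # the quadratic MSD coefficient is noisy on 10-s tracks: the honest
        # guarantees are a zero median and estimates well below the
        # transport speed for almost all tracks
        assert np.median(vs) == 0.0
        assert np.quantile(vs, 0.95) < 0.324

    def test_ensemble_recovers_transport_speed(self):
        cfg = sim.SceneConfig(
            n_puncta=200,
            n_frames=100,
            state_fractions={"directed": 1.0},
            seed=8,
            field_size_um=(100, 100),
        )
        m = {"directed": sim.MotionModel("directed", v=0.324, D=0.01, jitter_sd=0.02)}
        obs, _ = sim.simulate_trajectories(cfg, m, margin_um=6)
        vs = [directed_speed(obs[i], DT) for i in range(200)]
        assert abs(np.mean(vs) / 0.324 - 1) < 0.10


class TestOverlayImmobile:
    def _scene(self, fractions, seed):
        cfg = sim.SceneConfig(
            n_puncta=100,
            n_frames=2,
            frame_interval_s=30.0,
            state_fractions=fractions,
            seed=seed,
            field_size_um=(40.96, 40.96),
            noise_sd=2.0,
        )
        models = {
            "immobile": sim.MotionModel("immobile", jitter_sd=0.02),
            "diffusive": sim.MotionModel("diffusive", D=0.0308, jitter_sd=0.02),
        }
        obs, truth = sim.simulate_trajectories(cfg, models, margin_um=2)
        movie = sim.render_movie(obs, cfg, intensities=400.0)
        return movie, truth, cfg

    def test_static_punctum_immobile_and_moved_punctum_mobile(self):
        frame = np.full((64, 64), 100.0)
        yy, xx = np.mgrid[0:64, 0:64]
        g = lambda cx, cy: 50 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / 2.0)
        f0 = frame + g(20, 20) + g(40, 40)
        f1 = frame + g(20, 20) + g(47, 40)  # second punctum moved ~1.1 µm
        spots, frac = overlay_immobile(f0, f1, 0.16, 0.16, 30.0)
        assert len(spots) == 2
        assert sorted(spots["immobile"]) == [False, True]
        assert frac == pytest.approx(0.5)

    def test_planted_immobile_fraction_recovered_within_ci(self):
        movie, truth, _ = self._scene({"immobile": 0.26, "diffusive": 0.74}, 20)
        _, frac = overlay_immobile(movie.data[0], movie.data[1], 0.16, 0.16, 30.0)
        n = len(truth.puncta)
        half = 1.96 * np.sqrt(0.26 * 0.74 / n)
        # a diffusing punctum can linger within the match radius by chance,
        # so compare against the planted fraction at the binomial 95% CI
        assert abs(frac - 0.26) < half + 0.03

    def test_mismatched_geometry_raises(self):
        with pytest.raises(ValueError):
            overlay_immobile(np.zeros((10, 10)), np.zeros((12, 12)), 0.16, 0.16, 30.0)


class TestSummary:
    def test_single_cell_all_diffusive(self):
        out = mobility_summary([["diffusive"] * 8])
        assert out["pooled"]["diffusive"]["mean"] == 1.0

    def test_split_percentage_rounds_to_three(self):
        out = mobility_summary([["diffusive"]], n_split=133, n_total=4492)
        assert out["percent_split"] == 3

    def test_split_detects_motion_change(self):
        rng = np.random.default_rng(1)
        still = 5.0 + rng.normal(0, 0.01, (50, 2))
        moving = still[-1] + np.cumsum(
            np.full((50, 2), 0.8 * DT / np.sqrt(2)), axis=0
        )
        segments = split_by_motion_change(np.vstack([still, moving]), DT)
        assert len(segments) >= 2

    def test_uniform_motion_not_split(self):
        segments = split_by_motion_change(linear_track(n=100), DT)
        assert len(segments) == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.45, 1.5), st.floats(0.0, 2 * np.pi))
def test_directed_classification_scale_free(v, heading):
    """Any noise-free constant-velocity track fast enough to clear the
    40 nm/frame mobility floor is directed, whatever the heading."""
    prof = compute_msd(linear_track(v=v, heading=heading), DT)
    assert classify_trajectory(prof) == "directed"
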