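import numpy as np
import pytest

from punctakit import simulate as sim


@pytest.fixture(scope="session")
def brownian_tracks():
    """1000 pure-diffusion tracks at the reference D, jitter-free."""
    cfg = sim.SceneConfig(
        n_puncta=1000,
        n_frames=50,
        state_fractions={"diffusive": 1.0},
        seed=101,
        field_size_um=(300.0, 300.0),
    )
    models = {"diffusive": sim.MotionModel("diffusive", D=0.0308, jitter_sd=0.0)}
    obs, truth = sim.simulate_trajectories(cfg, models, margin_um=20)
    return obs, truth, cfg


@pytest.fixture(scope="session")
def rendered_single_spot():
    """One noise-free rendered spot at a known sub-pixel position."""
    cfg = sim.SceneConfig(
        field_size_um=(32 * 0.16, 32 * 0.16),
        noise_sd=0.0,
        n_frames=1,
        n_puncta=1,
        seed=0,
    )
    true_px = (10.25, 7.50)
    traj = np.array([[[true_px[0] * 0.16, true_px[1] * 0.16]]])
    movie = sim.render_movie(traj, cfg, intensities=500.0)
    return movie, true_px, cfg
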