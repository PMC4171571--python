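import numpy as np
import pytest

from streaklab import synth
from streaklab.presets import get_preset


@pytest.fixture(scope="session")
def act_chi():
    return get_preset("act_chi")


@pytest.fixture(scope="session")
def act_chi_tracks(act_chi):
    """A modest Act/Chi track population reused across motility tests."""
    return synth.simulate_trajectories(act_chi, 30, 60.0, 1.0 / 6.0, seed=11)


def make_brownian_tracks(d_values, n_frames=121, dt=1.0 / 6.0, seed=0):
    """Independent 2-D Brownian tracks with per-track diffusivity (μm²/h)."""
    rng = np.random.default_rng(seed)
    tracks = []
    for i, d in enumerate(np.atleast_1d(d_values)):
        steps = rng.normal(0.0, np.sqrt(2.0 * d * dt), size=(n_frames - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(synth.Track(f"bm{i:04d}", np.arange(n_frames) * dt,
                                  pos[:, 0], pos[:, 1]))
    return synth.TrackSet(tracks, condition="brownian", dt=dt,
                          duration=(n_frames - 1) * dt)


def straight_track(v_um_h=36.0, n_frames=61, dt=1.0 / 6.0, angle=0.0):
    """A ballistic track moving at constant speed along a fixed heading."""
    t = np.arange(n_frames) * dt
    return synth.Track("ballistic", t,
                       v_um_h * t * np.cos(angle),
                       v_um_h * t * np.sin(angle))
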