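"""Shared fixtures: small seeded synthetic tables used across the suite."""

import numpy as np
import pandas as pd
import pytest

from epidyn.synthetic import SyntheticParams, gen_trajectories
from epidyn.tracks import TrackTable


def make_table(pos: np.ndarray, dt: float = 5.0, theta: np.ndarray = None,
               **extra) -> TrackTable:
    """TrackTable from a (T, N, 2) position array (shifted to positive)."""
    pos = np.asarray(pos, float)
    T, N = pos.shape[:2]
    pos = pos - np.minimum(pos.reshape(-1, 2).min(axis=0), 0.0)
    df = pd.DataFrame({
        "track_id": np.tile(np.arange(N), T),
        "frame": np.repeat(np.arange(T), N),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
    })
    if theta is not None:
        df["theta"] = np.mod(np.asarray(theta, float), np.pi).ravel()
    for k, v in extra.items():
        df[k] = np.asarray(v).ravel()
    W = float(df["x"].max()) or 1.0
    H = float(df["y"].max()) or 1.0
    return TrackTable(df=df, dt=dt, field_width=W, field_height=H)


@pytest.fixture(scope="session")
def brownian_tracks() -> TrackTable:
    """1000 Brownian cells, D = 0.025 μm²/min, 120 frames."""
    p = SyntheticParams(n_cells=1000, field_width=400.0, field_height=400.0,
                        n_frames=120, model="brownian", D=0.025, rng_seed=11)
    return gen_trajectories(p)


@pytest.fixture(scope="session")
def trap_params() -> SyntheticParams:
    return SyntheticParams(n_cells=1200, field_width=450.0,
                           field_height=450.0, n_frames=325,
                           model="trap_creep", D_c=0.0125, sigma_s=1.5,
                           tau_r=200.0, rng_seed=12)


@pytest.fixture(scope="session")
def trap_tracks(trap_params) -> TrackTable:
    return gen_trajectories(trap_params)


@pytest.fixture(scope="session")
def static_tracks() -> TrackTable:
    rng = np.random.default_rng(3)
    pos0 = rng.uniform(0, 100, (50, 2))
    pos = np.repeat(pos0[None], 60, axis=0)
    return make_table(pos)
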