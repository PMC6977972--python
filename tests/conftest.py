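import numpy as np
import pandas as pd
import pytest

import smtpatch as sp


@pytest.fixture(scope="session")
def sparse_movie():
    """One rendered sparse movie (<= 3 visible molecules) with ground truth.

    Shared by detection, linking-fidelity and pipeline tests; 300 frames,
    64x64 px, gamma residence, moderate diffusion, peak SNR ~ 5-6.
    """
    params = sp.EmitterSimParams(
        field_size=64,
        duration=30.0,
        birth_rate=1.0,
        residence_model="gamma",
        residence_shape=2.0,
        residence_scale=1.0,
        diffusion_D=1000.0,
        bleach_rate=0.0,
        photons_per_frame=400.0,
        seed=11,
    )
    truth = sp.generate_truth_tracks(params)
    stack = sp.render_movie(truth, rng=12)
    return truth, stack


@pytest.fixture(scope="session")
def sparse_movie_locs(sparse_movie):
    truth, stack = sparse_movie
    return sp.localize_stack(stack, filter_spec=sp.LocFilterSpec())


def brownian_track_table(
    n_tracks: int,
    n_spots: int,
    D: float,
    loc_sigma: float,
    rng: np.random.Generator,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Long-format track table of pure 2D Brownian walks + Gaussian noise."""
    rows = []
    for tid in range(n_tracks):
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), (n_spots - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(0.0, loc_sigma, (n_spots, 2))
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "movie_id": 0,
                    "frame": np.arange(n_spots),
                    "t_s": np.arange(n_spots) * dt,
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def lifetime_track_table(
    start_times: np.ndarray,
    lifetimes: np.ndarray,
    dt: float = 0.1,
    movie_id: int = 0,
) -> pd.DataFrame:
    """Minimal two-spot tracks realizing given start times and lifetimes."""
    f0 = np.rint(np.asarray(start_times) / dt).astype(int)
    nfr = np.maximum(np.rint(np.asarray(lifetimes) / dt).astype(int), 2)
    f1 = f0 + nfr - 1
    tid = np.arange(len(f0))
    frames = np.ravel(np.c_[f0, f1])
    return pd.DataFrame(
        {
            "track_id": np.repeat(tid, 2),
            "movie_id": movie_id,
            "frame": frames,
            "t_s": frames * dt,
            "x_nm": 0.0,
            "y_nm": 0.0,
        }
    )
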