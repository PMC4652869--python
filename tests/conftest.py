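"""Shared fixtures: simulated ensembles reused across test modules.

The Roessler ensembles are the expensive part of the suite (ten
16000-sample trajectories with full embeddedness profiles in both
orientations), so they are computed once per session and shared by the
directionality, complexity and convergence tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossembed.crossmap import ForecastSpec, embeddedness_profile
from crossembed.embedding import EmbeddingConfig
from crossembed.simulators import RosslerParams, simulate_coupled_rossler

N_SEEDS = 10
#: analysis settings of the Roessler validation studies: unit delay 4
#: samples, maximum dimension 20, k = 4, order-10^4 samples per channel
ROSSLER_EMB = dict(tau=4, d_max=20)


def rossler_series(seed: int, coupled: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(downstream xi1, upstream xi2) for one seed, 16000 samples each."""
    traj = simulate_coupled_rossler(RosslerParams(seed=seed, coupled=coupled))
    return traj.observables[:, 0], traj.observables[:, 1]


def _profile_pair(x_down, y_up, seed):
    emb = EmbeddingConfig(seed=seed, **ROSSLER_EMB)
    spec = ForecastSpec(query_seed=seed)
    p_up_by_down = embeddedness_profile(
        x_down, y_up, emb, spec, direction=("down", "up")
    )
    p_down_by_up = embeddedness_profile(
        y_up, x_down, emb, spec, direction=("up", "down")
    )
    return p_up_by_down, p_down_by_up


@pytest.fixture(scope="session")
def rossler_coupled_runs():
    """Per-seed coupled trajectories with both embeddedness profiles."""
    runs = []
    for s in range(N_SEEDS):
        x, y = rossler_series(s, coupled=True)
        p1, p2 = _profile_pair(x, y, s)
        runs.append({
            "seed": s, "x": x, "y": y,
            "up_by_down": p1, "down_by_up": p2,
        })
    return runs


@pytest.fixture(scope="session")
def rossler_uncoupled_runs():
    """Per-seed uncoupled control trajectories with both profiles."""
    runs = []
    for s in range(N_SEEDS):
        x, y = rossler_series(s, coupled=False)
        p1, p2 = _profile_pair(x, y, s)
        runs.append({
            "seed": s, "x": x, "y": y,
            "up_by_down": p1, "down_by_up": p2,
        })
    return runs


@pytest.fixture(scope="session")
def short_rossler():
    """One small coupled trajectory (2000 samples) for cheap unit tests."""
    traj = simulate_coupled_rossler(
        RosslerParams(seed=7, duration=300.0, transient=100.0)
    )
    return traj.observables[:, 0], traj.observables[:, 1]
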