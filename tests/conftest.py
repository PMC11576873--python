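"""Shared fixtures: small synthetic videos and heavier session-scoped
artefacts (the default synthetic cohort, run once and reused)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from infantstates import arhmm
from infantstates.keypoint_io import BODY_POINTS, N_POINTS, VideoTrajectory
from infantstates.synthetic import (
    SKELETON,
    GeneratorSpec,
    default_truth,
    make_default_fixture,
    simulate_video,
)

warnings.filterwarnings("ignore", message=".*IterativeImputer.*")


def skeleton_trajectory(
    n_frames: int = 100, fps: float = 25.0, jitter: float = 0.0, seed: int = 0
) -> VideoTrajectory:
    """Static canonical skeleton video, optionally with Gaussian jitter."""
    rng = np.random.default_rng(seed)
    template = np.array([SKELETON[bp] for bp in BODY_POINTS])
    xy = np.tile(template[None], (n_frames, 1, 1)).astype(float)
    if jitter:
        xy = xy + rng.normal(0.0, jitter, xy.shape)
    conf = np.ones((n_frames, N_POINTS))
    return VideoTrajectory(
        video_id="skel", participant_id="p0", fps=fps, xy=xy, confidence=conf
    )


@pytest.fixture(scope="session")
def recovery_truth() -> arhmm.ARHMMParams:
    """Well-separated K=3, L=2, d=4 ground-truth model."""
    return default_truth(K=3, L=2, d=4, seed=7)


@pytest.fixture(scope="session")
def recovery_data(recovery_truth):
    """20 sequences x 1799 frames sampled from the recovery model."""
    xs, zs = [], []
    for i in range(20):
        x, z = arhmm.sample(recovery_truth, 1799, seed=100 + i)
        xs.append(x)
        zs.append(z)
    return xs, zs


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    xs, _ = recovery_data
    return arhmm.fit_em(xs, K=3, L=2, max_iter=200, tol=1e-6, seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """The deterministic default synthetic cohort (30 participants)."""
    return make_default_fixture(seed=0)


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    """Full preprocessing of the default cohort (the slow shared step)."""
    from infantstates.preprocess import preprocess_cohort

    results, stats = preprocess_cohort(default_cohort.trajectories)
    poses = [r.pose for r in results if r.pose is not None]
    return poses, stats, results


@pytest.fixture(scope="session")
def pm_projection(default_cohort, preprocessed_cohort):
    """PM basis + per-video velocity series at the package default k=15."""
    from infantstates.principal_movements import fit_pm_basis, project

    poses, _, _ = preprocessed_cohort
    pid = {t.video_id: t.participant_id for t in default_cohort.trajectories}
    basis = fit_pm_basis(
        poses, n_videos=min(30, len(poses)), participant_ids=pid, seed=0
    )
    series = [project(p, basis, k=15) for p in poses]
    return basis, series
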