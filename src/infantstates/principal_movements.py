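"""Principal movements: an SVD basis over pooled, normalised pose features.

Each video's t x 36 feature matrix is demeaned and scaled to unit SD per
feature (per video, removing residual position/size differences), the
videos are concatenated along time and decomposed as ``M = U S V^T``.
Columns of V are pose eigenvectors ("principal movements"); the weights
``U S`` measure how far the posture at each frame deviates from the mean
pose along each eigenvector.  Downstream models operate on the first
difference (velocity) of the truncated weight series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import PoseMatrix


@dataclass
class PMBasis:
    """Fitted pose-eigenvector basis.

    ``V`` has orthonormal columns (36 x 36); ``singular_values`` come from
    the pooled SVD; ``variance_explained`` is per-component and sums to 1.
    """

    V: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    n_fit_videos: int
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float)
        self.singular_values = np.asarray(self.singular_values, float)
        self.variance_explained = np.asarray(self.variance_explained, float)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "V": self.V.tolist(),
            "singular_values": self.singular_values.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "n_fit_videos": self.n_fit_videos,
            "feature_names": list(self.feature_names),
            "schema": "infantstates.pm_basis.v1",
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PMBasis":
        payload = json.loads(Path(path).read_text())
        return cls(
            V=np.array(payload["V"]),
            singular_values=np.array(payload["singular_values"]),
            variance_explained=np.array(payload["variance_explained"]),
            n_fit_videos=payload["n_fit_videos"],
            feature_names=tuple(payload["feature_names"]),
        )


@dataclass
class PMSeries:
    """Per-video weight timeseries and its first difference (velocity)."""

    weights: np.ndarray  # (t, k)
    velocity: np.ndarray  # (t-1, k)
    video_id: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.velocity = np.asarray(self.velocity, float)
        if self.velocity.shape[0] != self.weights.shape[0] - 1:
            raise ValueError("velocity must have one fewer row than weights")


def _normalise_video(M: np.ndarray, video_id: str) -> np.ndarray:
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    zero = sd <= 1e-12 * (1.0 + np.abs(mean))
    if np.any(zero):
        bad = int(np.flatnonzero(zero)[0])
        raise ValueError(
            f"video {video_id}: feature {bad} is constant (zero SD); cannot normalise"
        )
    return (M - mean) / sd


def fit_pm_basis(
    videos: list[PoseMatrix],
    n_videos: int = 100,
    one_per_participant: bool = True,
    participant_ids: dict[str, str] | None = None,
    seed: int = 0,
) -> PMBasis:
    """Fit the pose-eigenvector basis on a seeded random subset of videos.

    With ``one_per_participant`` a single video per participant is drawn
    (``participant_ids`` maps video_id -> participant_id; identity when
    absent).  Each selected video is demeaned and scaled to unit SD per
    feature before concatenation along time and SVD.
    """
    rng = np.random.default_rng(seed)
    if one_per_participant:
        groups: dict[str, list[PoseMatrix]] = {}
        for v in videos:
            pid = (participant_ids or {}).get(v.video_id, v.video_id)
            groups.setdefault(pid, []).append(v)
        if len(groups) < n_videos:
            raise ValueError(
                f"need >= {n_videos} distinct participants, have {len(groups)}"
            )
        pids = sorted(groups)
        chosen_pids = rng.choice(len(pids), size=n_videos, replace=False)
        selected = [
            groups[pids[i]][rng.integers(len(groups[pids[i]]))] for i in chosen_pids
        ]
    else:
        if len(videos) < n_videos:
            raise ValueError(f"need >= {n_videos} videos, have {len(videos)}")
        idx = rng.choice(len(videos), size=n_videos, replace=False)
        selected = [videos[i] for i in idx]

    blocks = [_normalise_video(v.M, v.video_id) for v in selected]
    concat = np.concatenate(blocks, axis=0)
    _, s, vt = np.linalg.svd(concat, full_matrices=False)
    V = vt.T
    # resolve SVD sign ambiguity: largest-|.| element of each column positive
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    var = s**2
    var = var / var.sum()
    return PMBasis(
        V=V,
        singular_values=s,
        variance_explained=var,
        n_fit_videos=len(selected),
        feature_names=selected[0].feature_names,
    )


def project(M: PoseMatrix, basis: PMBasis, k: int = 15) -> PMSeries:
    """Project a video onto the first ``k`` principal movements.

    The video is normalised (its own per-feature mean/SD) and multiplied by
    the eigenvectors; velocity is the raw first difference per frame.
    """
    if k < 1 or k > basis.V.shape[1]:
        raise ValueError(f"k must lie in [1, {basis.V.shape[1]}], got {k}")
    Mn = _normalise_video(M.M, M.video_id)
    weights = Mn @ basis.V[:, :k]
    return PMSeries(weights=weights, velocity=np.diff(weights, axis=0), video_id=M.video_id)


def reconstruct(series_weights: np.ndarray, basis: PMBasis) -> np.ndarray:
    """Map weights back to (normalised) feature space: W @ V[:, :k].T."""
    k = series_weights.shape[1]
    return series_weights @ basis.V[:, :k].T


def variance_explained(basis: PMBasis, k: int) -> float:
    """Cumulative fraction of pose variance captured by the first k components."""
    n = basis.variance_explained.shape[0]
    if k < 0 or k > n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    return float(basis.variance_explained[:k].sum())
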