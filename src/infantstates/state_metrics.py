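"""Summaries of decoded state sequences.

Occupancy (fraction of frames per state), bout counts (maximal runs),
dwell statistics (pooled median run length excluding single-frame runs,
and the longest run), and high-velocity specificity: which states soak up
the fastest frames of each body-part cluster (arms / legs / head).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keypoint_io import BODY_POINTS, N_POINTS

#: Default body-part clusters for high-velocity specificity.
DEFAULT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "arms": (
        "left_shoulder", "right_shoulder",
        "left_elbow", "right_elbow",
        "left_wrist", "right_wrist",
    ),
    "legs": (
        "left_hip", "right_hip",
        "left_knee", "right_knee",
        "left_heel", "right_heel",
        "left_hallux", "right_hallux",
    ),
    "head": ("crown", "chin", "left_eye", "right_eye"),
}


def occupancy(labels: np.ndarray, K: int) -> np.ndarray:
    """Fraction of frames spent in each state (sums to 1)."""
    labels = np.asarray(labels, int)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels must lie in 0..{K - 1}")
    return np.bincount(labels, minlength=K) / labels.size


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run decomposition: (state of each run, length of each run)."""
    labels = np.asarray(labels, int)
    if labels.size == 0:
        return np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


@dataclass
class RunLengthStats:
    per_state: dict[int, np.ndarray]
    median_run_length: float  # pooled across states, runs of length >= 2 only
    max_dwell: int


def run_length_stats(labels: np.ndarray, K: int) -> RunLengthStats:
    """Dwell statistics from the maximal-run decomposition.

    The median pools runs of length >= 2 across all states (single-frame
    instances excluded); max dwell is the longest run in the sequence.
    """
    states, lengths = run_lengths(labels)
    per_state = {k: lengths[states == k] for k in range(K)}
    ge2 = lengths[lengths >= 2]
    med = float(np.median(ge2)) if ge2.size else float("nan")
    mx = int(lengths.max()) if lengths.size else 0
    return RunLengthStats(per_state=per_state, median_run_length=med, max_dwell=mx)


def bout_counts(labels: np.ndarray, K: int, min_len: int = 1) -> np.ndarray:
    """Number of maximal runs of length >= min_len per state."""
    states, lengths = run_lengths(labels)
    keep = lengths >= min_len
    return np.bincount(states[keep], minlength=K).astype(int)


def bodypoint_displacements(coords: np.ndarray) -> np.ndarray:
    """Frame-to-frame displacement magnitude per body point.

    ``coords`` is (t, 18, 2) in body-length units on the 10 Hz grid;
    returns (t-1, 18).
    """
    coords = np.asarray(coords, float)
    return np.linalg.norm(np.diff(coords, axis=0), axis=2)


def high_velocity_by_state(
    displacements: list[np.ndarray],
    labels: list[np.ndarray],
    K: int,
    quantile: float = 0.90,
    clusters: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Fraction of each body-part cluster's high-velocity frames per state.

    Per body point, frames whose displacement exceeds the cohort-pooled
    ``quantile`` are tagged; tags are mapped to the decoded state of the
    frame and aggregated per cluster and state for each video.  Fractions
    sum to 1 over states within a cluster; a video with no tagged frames
    in a cluster gets NaN for that cluster.
    """
    clusters = clusters or DEFAULT_CLUSTERS
    name_to_idx = {bp: i for i, bp in enumerate(BODY_POINTS)}
    for cname, members in clusters.items():
        unknown = [m for m in members if m not in name_to_idx]
        if unknown:
            raise ValueError(f"cluster {cname!r} references unknown body points {unknown}")
    pooled = np.concatenate(displacements, axis=0)  # (sum_t, 18)
    thresh = np.quantile(pooled, quantile, axis=0)  # per body point

    rows = []
    for vid, (disp, z) in enumerate(zip(displacements, labels)):
        z = np.asarray(z, int)
        zd = z[1:] if z.shape[0] == disp.shape[0] + 1 else z
        if zd.shape[0] != disp.shape[0]:
            raise ValueError("labels and displacements length mismatch")
        for cname, members in clusters.items():
            idx = [name_to_idx[m] for m in members]
            tagged = disp[:, idx] > thresh[idx][None, :]
            counts = np.zeros(K)
            frames, _ = np.nonzero(tagged)
            if frames.size:
                counts = np.bincount(zd[frames], minlength=K).astype(float)
                fracs = counts / counts.sum()
            else:
                fracs = np.full(K, np.nan)
            for k in range(K):
                rows.append(
                    {"video": vid, "cluster": cname, "state": k, "fraction": fracs[k]}
                )
    return pd.DataFrame(rows)


def state_displacement_sample(
    displacement_vectors: list[np.ndarray],
    labels: list[np.ndarray],
    K: int,
    n: int = 5000,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Seeded uniform sample of per-state displacement vectors (for plots).

    ``displacement_vectors`` holds per-video (t-1, 18, 2) frame-to-frame
    displacements.  Returns, per state, up to n sampled (18, 2) vectors.
    States with zero decoded frames yield an empty array (with a warning).
    """
    rng = np.random.default_rng(seed)
    per_state_pool: dict[int, list[np.ndarray]] = {k: [] for k in range(K)}
    for disp, z in zip(displacement_vectors, labels):
        z = np.asarray(z, int)
        zd = z[1:] if z.shape[0] == disp.shape[0] + 1 else z
        for k in range(K):
            sel = zd == k
            if sel.any():
                per_state_pool[k].append(disp[sel])
    out: dict[int, np.ndarray] = {}
    for k in range(K):
        if not per_state_pool[k]:
            import warnings

            warnings.warn(f"state {k} has zero decoded frames", RuntimeWarning)
            out[k] = np.empty((0, N_POINTS, 2))
            continue
        pool = np.concatenate(per_state_pool[k], axis=0)
        if pool.shape[0] <= n:
            out[k] = pool
        else:
            out[k] = pool[rng.choice(pool.shape[0], n, replace=False)]
    return out


@dataclass
class StateSummary:
    """Per-video expression summary used by the association stage."""

    video_id: str
    occupancy: np.ndarray
    bout_count: np.ndarray
    median_run_length: float
    max_dwell: int


def summarise_video(labels: np.ndarray, K: int, video_id: str = "") -> StateSummary:
    rl = run_length_stats(labels, K)
    return StateSummary(
        video_id=video_id,
        occupancy=occupancy(labels, K),
        bout_count=bout_counts(labels, K),
        median_run_length=rl.median_run_length,
        max_dwell=rl.max_dwell,
    )


def summaries_to_frame(summaries: list[StateSummary]) -> pd.DataFrame:
    """One row per video with occupancy_k / bout_count_k columns."""
    rows = []
    for s in summaries:
        row = {"video_id": s.video_id,
               "median_run_length": s.median_run_length,
               "max_dwell": s.max_dwell}
        for k, v in enumerate(s.occupancy):
            row[f"occupancy_{k}"] = v
        for k, v in enumerate(s.bout_count):
            row[f"bout_count_{k}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)
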