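"""Reading, writing and frame-rate standardisation of keypoint trajectories.

Keypoint tables follow the common markerless-pose CSV dialect with a
three-row header (scorer / bodyparts / coords) and one row per video frame;
each body point contributes ``x``, ``y`` and ``likelihood`` columns.  A
missing observation is stored as empty/NaN coordinates with confidence 0.

Cohort metadata is a flat CSV with one row per video (participant id,
video id, corrected age in weeks, birth status, general-movements
classification and optional 2-year Bayley-III composite scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The 18 tracked body points, in canonical column order.
BODY_POINTS: tuple[str, ...] = (
    "crown",
    "left_eye",
    "right_eye",
    "chin",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_heel",
    "right_heel",
    "left_hallux",
    "right_hallux",
)

N_POINTS = len(BODY_POINTS)

#: Feature names for the flattened t x 36 pose representation
#: (body-point major, x before y).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{bp}_{ax}" for bp in BODY_POINTS for ax in ("x", "y")
)


class KeypointFormatError(ValueError):
    """Raised when a keypoint table does not parse under the dialect."""


@dataclass
class VideoTrajectory:
    """Raw per-frame keypoint coordinates and confidences for one video.

    Attributes
    ----------
    video_id, participant_id : str
        Identifiers carried through the pipeline.
    fps : float
        Acquisition frame rate (frames per second), > 0.
    xy : ndarray, shape (T, 18, 2)
        Pixel coordinates; a missing observation is NaN in both axes.
    confidence : ndarray, shape (T, 18)
        Per-frame labelling confidence in [0, 1]; 0 for missing points.
    """

    video_id: str
    participant_id: str
    fps: float
    xy: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_POINTS, 2):
            raise ValueError(
                f"xy must have shape (T, {N_POINTS}, 2), got {self.xy.shape}"
            )
        if self.xy.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.confidence.shape != self.xy.shape[:2]:
            raise ValueError("confidence shape must match xy frames x points")
        with np.errstate(invalid="ignore"):
            bad = (self.confidence < 0) | (self.confidence > 1)
        if np.any(bad & np.isfinite(self.confidence)):
            raise ValueError("confidences must lie in [0, 1]")
        # x and y are jointly missing: NaN in one axis implies NaN in both
        nan_xy = np.isnan(self.xy)
        mixed = nan_xy[..., 0] != nan_xy[..., 1]
        if np.any(mixed):
            self.xy[mixed] = np.nan
        # convention: a missing observation carries confidence 0
        self.confidence[np.isnan(self.xy[..., 0])] = 0.0

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (T, 18) mask of missing observations."""
        return np.isnan(self.xy[..., 0])

    def copy(self) -> "VideoTrajectory":
        return replace(self, xy=self.xy.copy(), confidence=self.confidence.copy())


@dataclass
class CohortTable:
    """Cohort metadata: one row per video.

    Columns: participant_id, video_id, corrected_age (weeks), birth_status
    ('preterm'/'term'), gm_class ('normal'/'abnormal_or_absent'/NaN) and
    optional bayley_motor/bayley_cognitive/bayley_language composites.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = (
        "participant_id",
        "video_id",
        "corrected_age",
        "birth_status",
        "gm_class",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        counts = self.frame.groupby("participant_id")["video_id"].nunique()
        if (counts > 2).any():
            bad = counts[counts > 2].index.tolist()
            raise ValueError(f"participants with >2 videos: {bad}")


def read_keypoint_table(
    path: str | Path,
    *,
    video_id: str | None = None,
    participant_id: str | None = None,
    fps: float = 25.0,
) -> VideoTrajectory:
    """Read a 3-row-header keypoint CSV into a :class:`VideoTrajectory`.

    Unparseable coordinate cells become missing observations (NaN x/y,
    confidence 0).  The body-point set must match :data:`BODY_POINTS`
    exactly; the per-point column triplet must be (x, y, likelihood).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise KeypointFormatError(f"{path}: malformed header ({exc})") from exc
    if df.columns.nlevels != 3:
        raise KeypointFormatError(f"{path}: expected a 3-row header")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    unknown = set(bodyparts) - set(BODY_POINTS)
    if unknown:
        raise KeypointFormatError(f"{path}: unknown body points {sorted(unknown)}")
    if set(bodyparts) != set(BODY_POINTS):
        raise KeypointFormatError(
            f"{path}: expected {N_POINTS} body points, found {len(bodyparts)}"
        )
    scorer = df.columns.get_level_values(0)[0]
    T = len(df)
    xy = np.full((T, N_POINTS, 2), np.nan)
    conf = np.zeros((T, N_POINTS))
    for i, bp in enumerate(BODY_POINTS):
        for j, coord in enumerate(("x", "y")):
            try:
                col = df[(scorer, bp, coord)]
            except KeyError as exc:
                raise KeypointFormatError(
                    f"{path}: missing column {bp}/{coord}"
                ) from exc
            xy[:, i, j] = pd.to_numeric(col, errors="coerce").to_numpy()
        try:
            like = df[(scorer, bp, "likelihood")]
            conf[:, i] = pd.to_numeric(like, errors="coerce").fillna(0.0).to_numpy()
        except KeyError as exc:
            raise KeypointFormatError(
                f"{path}: missing column {bp}/likelihood"
            ) from exc
    # jointly missing convention; missing points have confidence 0
    miss = np.isnan(xy).any(axis=2)
    xy[miss] = np.nan
    conf[miss] = 0.0
    return VideoTrajectory(
        video_id=video_id or path.stem,
        participant_id=participant_id or path.stem,
        fps=fps,
        xy=xy,
        confidence=conf,
    )


def write_keypoint_table(
    traj: VideoTrajectory, path: str | Path, scorer: str = "infantstates"
) -> Path:
    """Write a trajectory in the 3-row-header CSV dialect (inverse of read)."""
    path = Path(path)
    cols = pd.MultiIndex.from_tuples(
        [(scorer, bp, c) for bp in BODY_POINTS for c in ("x", "y", "likelihood")],
        names=("scorer", "bodyparts", "coords"),
    )
    T = traj.n_frames
    data = np.empty((T, N_POINTS * 3))
    data[:, 0::3] = traj.xy[..., 0]
    data[:, 1::3] = traj.xy[..., 1]
    data[:, 2::3] = traj.confidence
    pd.DataFrame(data, columns=cols).to_csv(path, index=True, index_label=None)
    return path


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.frame.to_csv(path, index=False)
    return path


def standardise_frame_rate(
    traj: VideoTrajectory, target_fps: float = 25.0, duration_s: float = 180.0
) -> VideoTrajectory:
    """Resample a trajectory onto a uniform ``target_fps`` grid.

    The output grid is half-open [0, duration) with frame ``i`` at time
    ``i / target_fps`` (so 180 s at 25 fps gives exactly 4500 frames).
    Coordinates are linearly interpolated in time; a target frame is
    missing when either bracketing source frame is missing, so missing
    spans are preserved rather than bridged.  Confidences are carried
    from the nearest source frame.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    n_out = int(round(target_fps * duration_s))
    t_src = np.arange(traj.n_frames) / traj.fps
    t_tgt = np.arange(n_out) / target_fps

    left = np.searchsorted(t_src, t_tgt, side="right") - 1
    left = np.clip(left, 0, traj.n_frames - 1)
    right = np.clip(left + 1, 0, traj.n_frames - 1)
    denom = t_src[right] - t_src[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (t_tgt - t_src[left]) / np.where(denom == 0, 1, denom), 0.0)
    w = np.clip(w, 0.0, 1.0)

    xl = traj.xy[left]  # (n_out, 18, 2)
    xr = traj.xy[right]
    xy = xl * (1 - w)[:, None, None] + xr * w[:, None, None]
    # either bracket missing -> missing (NaN already propagates through the blend)

    nearest = np.where(w > 0.5, right, left)
    conf = traj.confidence[nearest]
    conf[np.isnan(xy[..., 0])] = 0.0
    return replace(traj, fps=float(target_fps), xy=xy, confidence=conf)
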