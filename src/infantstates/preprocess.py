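"""Cleaning pipeline from raw keypoint trajectories to pose-feature matrices.

The stages, in order: confidence filter -> labelling-quality gate ->
two-step ellipse outlier removal -> gap filling -> camera alignment ->
body-length scaling -> feature extraction -> zero-phase band-pass ->
cohort-level outlier masking -> spline downsampling to 10 Hz.

All geometry is 2-D image-plane geometry.  "Infant length" is the
video-median crown-to-mid-hip distance; the mid-hip (mean of the two hip
points) anchors the body frame and the mid-hip -> mid-shoulder axis
defines torso orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .keypoint_io import BODY_POINTS, FEATURE_NAMES, N_POINTS, VideoTrajectory

_CROWN = BODY_POINTS.index("crown")
_LHIP = BODY_POINTS.index("left_hip")
_RHIP = BODY_POINTS.index("right_hip")
_LSHO = BODY_POINTS.index("left_shoulder")
_RSHO = BODY_POINTS.index("right_shoulder")


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the cleaning pipeline (defaults as used throughout)."""

    confidence_threshold: float = 0.2
    min_labelled_fraction: float = 0.70
    body_ellipse_axes: tuple[float, float] = (1.5, 1.0)  # x infant length, along/across torso
    point_ellipse_scale: float = 5.0  # x per-axis MAD
    linear_gap_max: int = 5  # strict upper bound on linearly filled gap length
    impute_max_iter: int = 10
    band: tuple[float, float] = (0.01, 5.0)  # Hz
    filter_order: int = 4
    cohort_sd_k: float = 3.0
    target_fps: float = 25.0
    duration_s: float = 180.0
    downsample_len: int = 1800


@dataclass
class PoseMatrix:
    """Cleaned, normalised pose features for one video (t x 36)."""

    M: np.ndarray
    video_id: str
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != len(self.feature_names):
            raise ValueError(f"expected t x {len(self.feature_names)} matrix")

    @property
    def coords(self) -> np.ndarray:
        """View of the features as (t, 18, 2) keypoint coordinates."""
        return self.M.reshape(self.M.shape[0], N_POINTS, 2)


@dataclass
class CohortStats:
    """Per-feature cohort median and standard deviation (about the median)."""

    median: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.median.shape != (len(self.feature_names),):
            raise ValueError("median shape mismatch")
        if self.sd.shape != self.median.shape:
            raise ValueError("sd shape mismatch")
        if np.any(self.sd <= 0):
            raise ValueError("cohort standard deviations must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "median": self.median, "sd": self.sd}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortStats":
        return cls(
            median=df["median"].to_numpy(),
            sd=df["sd"].to_numpy(),
            feature_names=tuple(df["feature"]),
        )


@dataclass
class QualityReport:
    video_id: str
    labelled_fraction: float
    passed: bool


# ---------------------------------------------------------------------------
# stage 1-2: confidence filter and quality gate

def filter_low_confidence(
    traj: VideoTrajectory, threshold: float = 0.2
) -> VideoTrajectory:
    """Remove observations with confidence strictly below ``threshold``."""
    out = traj.copy()
    low = out.confidence < threshold
    out.xy[low] = np.nan
    out.confidence[low] = 0.0
    return out


def video_quality_gate(
    traj: VideoTrajectory, min_labelled_fraction: float = 0.70
) -> QualityReport:
    """Fail a video whose mean labelled-point fraction falls below threshold."""
    if traj.n_frames == 0:
        raise ValueError("cannot gate a zero-frame trajectory")
    frac = float(np.mean(~traj.missing))
    return QualityReport(
        video_id=traj.video_id,
        labelled_fraction=frac,
        passed=frac >= min_labelled_fraction,
    )


# ---------------------------------------------------------------------------
# stage 3: two-step ellipse outliers

def _mid(traj_xy: np.ndarray, i: int, j: int) -> np.ndarray:
    return 0.5 * (traj_xy[:, i] + traj_xy[:, j])


def _complete_series(arr: np.ndarray) -> np.ndarray:
    """Fill NaNs in a (T, 2) series by temporal linear interpolation
    (clamped at the ends).  Interpolation commutes with affine maps of the
    plane, keeping downstream geometry equivariant under global camera
    transforms; a coordinate-wise median fallback would not."""
    out = arr.copy()
    t = np.arange(arr.shape[0], dtype=float)
    for j in range(arr.shape[1]):
        ok = np.isfinite(arr[:, j])
        if not ok.any():
            raise ValueError("anchor points missing in every frame")
        if not ok.all():
            out[~ok, j] = np.interp(t[~ok], t[ok], arr[ok, j])
    return out


def infant_length(traj: VideoTrajectory) -> float:
    """Video-median crown-to-mid-hip distance (pixels or current units)."""
    midhip = _mid(traj.xy, _LHIP, _RHIP)
    d = np.linalg.norm(traj.xy[:, _CROWN] - midhip, axis=1)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("infant length not computable: crown or hips never labelled")
    return float(np.median(d))


def detect_outliers_two_step(
    traj: VideoTrajectory, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Flag gross mislabels with a whole-body and a per-keypoint ellipse.

    Step 1 flags observations outside an ellipse centred on the per-frame
    mid-hip with semi-axes ``body_ellipse_axes`` x infant length along and
    across the torso axis.  Step 2 flags observations outside a per-keypoint
    ellipse centred on the keypoint's temporal median with per-axis semi-axes
    ``point_ellipse_scale`` x the median absolute deviation.  Returns a
    boolean (T, 18) mask, True = outlier.
    """
    cfg = cfg or PreprocessConfig()
    T = traj.n_frames
    length = infant_length(traj)
    mask = np.zeros((T, N_POINTS), dtype=bool)

    # frames with missing anchors use temporally interpolated positions
    centre = _complete_series(_mid(traj.xy, _LHIP, _RHIP))
    axis_pt = _complete_series(_mid(traj.xy, _LSHO, _RSHO))
    v = axis_pt - centre
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    u = v / norm  # torso direction per frame
    perp = np.stack([-u[:, 1], u[:, 0]], axis=1)
    a = cfg.body_ellipse_axes[0] * length
    b = cfg.body_ellipse_axes[1] * length

    rel = traj.xy - centre[:, None, :]
    along = np.einsum("tpd,td->tp", rel, u)
    across = np.einsum("tpd,td->tp", rel, perp)
    with np.errstate(invalid="ignore"):
        step1 = (along / a) ** 2 + (across / b) ** 2 > 1.0
    mask |= np.nan_to_num(step1, nan=False).astype(bool)

    # step 2: per-keypoint ellipse on temporal medians, robust per-axis scale.
    # evaluated in the torso-aligned body frame (axes along/across the torso)
    # so flagging is equivariant under global rotation of the camera
    body = np.stack(
        [np.einsum("tpd,td->tp", rel, perp), np.einsum("tpd,td->tp", rel, u)],
        axis=-1,
    )  # (T, 18, 2): across/along coordinates relative to the mid-hip
    med = np.nanmedian(body, axis=0)  # (18, 2)
    mad = np.nanmedian(np.abs(body - med[None]), axis=0)  # (18, 2)
    mad = np.maximum(mad, 1e-3 * length)  # floor so static points tolerate jitter
    r = cfg.point_ellipse_scale
    with np.errstate(invalid="ignore"):
        step2 = (
            ((body[..., 0] - med[None, :, 0]) / (r * mad[None, :, 0])) ** 2
            + ((body[..., 1] - med[None, :, 1]) / (r * mad[None, :, 1])) ** 2
            > 1.0
        )
    mask |= np.nan_to_num(step2, nan=False).astype(bool)
    mask &= ~traj.missing  # only observed points can be outliers
    return mask


def apply_outlier_mask(traj: VideoTrajectory, mask: np.ndarray) -> VideoTrajectory:
    out = traj.copy()
    out.xy[mask] = np.nan
    out.confidence[mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# stage 4: gap filling

def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    runs = []
    T = isnan.size
    t = 0
    while t < T:
        if isnan[t]:
            s = t
            while t < T and isnan[t]:
                t += 1
            runs.append((s, t))
        else:
            t += 1
    return runs


def _body_frame_transform(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-frame (centre, rotation) + global scale from observed anchors.

    Frames with missing anchors use temporally interpolated positions, so
    the transform is a deterministic, affine-equivariant function of the
    observed data.
    """
    centre = _complete_series(0.5 * (xy[:, _LHIP] + xy[:, _RHIP]))
    axis_pt = _complete_series(0.5 * (xy[:, _LSHO] + xy[:, _RSHO]))
    v = axis_pt - centre
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    u = v / norm
    # rotation per frame mapping torso axis to +y: rows of [[c,-s],[s,c]]
    c, s = u[:, 1], u[:, 0]
    R = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], axis=1)  # (T,2,2)
    d = np.linalg.norm(xy[:, _CROWN] - centre, axis=1)
    d = d[np.isfinite(d)]
    scale = float(np.median(d)) if d.size else 1.0
    return centre, R, max(scale, 1e-12)


def fill_gaps(
    traj: VideoTrajectory, linear_max: int = 5, impute_max_iter: int = 10
) -> VideoTrajectory:
    """Fill missing observations: short gaps linearly, long gaps by imputation.

    Interior gaps strictly shorter than ``linear_max`` frames are filled by
    per-coordinate linear interpolation.  Remaining gaps (long interior gaps
    and gaps touching the ends of the video) are filled by round-robin
    iterative multivariate imputation using all other coordinates as
    predictors, with values clipped to each feature's observed range.

    The imputation runs in the canonical body frame (torso-aligned,
    body-length units, computed from observed anchor points) and imputed
    values are mapped back, so gap filling commutes with global rotation,
    translation and scaling of the input.
    """
    X = traj.xy.reshape(traj.n_frames, -1).copy()  # (T, 36)
    T, D = X.shape
    for j in range(D):
        col = X[:, j]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        if isnan.all():
            raise ValueError(
                f"feature {FEATURE_NAMES[j]} missing in every frame; cannot fill"
            )
        for s, e in _nan_runs(isnan):
            if (e - s) < linear_max and s > 0 and e < T:
                col[s:e] = np.interp(
                    np.arange(s, e), [s - 1, e], [col[s - 1], col[e]]
                )
        X[:, j] = col
    if np.isnan(X).any():
        xy = X.reshape(T, N_POINTS, 2)
        centre, R, scale = _body_frame_transform(xy)
        body = np.einsum("tij,tpj->tpi", R, xy - centre[:, None, :]) / scale
        B = body.reshape(T, D)
        lo = np.nanmin(B, axis=0)
        hi = np.nanmax(B, axis=0)
        pad = 1e-9 + 1e-6 * (hi - lo)  # keep constant features valid for clipping
        imputer = IterativeImputer(
            max_iter=impute_max_iter,
            tol=1e-3,
            min_value=lo - pad,
            max_value=hi + pad,
            random_state=0,
            sample_posterior=False,
        )
        B = imputer.fit_transform(B)
        if B.shape[1] != D:  # a column was dropped as empty
            raise ValueError("imputation dropped a feature; input degenerate")
        body = B.reshape(T, N_POINTS, 2)
        filled = (
            np.einsum("tji,tpj->tpi", R, scale * body) + centre[:, None, :]
        )
        X = np.where(np.isnan(X), filled.reshape(T, D), X)
    out = traj.copy()
    out.xy = X.reshape(T, N_POINTS, 2)
    out.confidence = np.where(traj.missing, 0.0, traj.confidence)
    return out


# ---------------------------------------------------------------------------
# stage 5-6: camera alignment and scaling

def align_camera(traj: VideoTrajectory) -> VideoTrajectory:
    """Move each frame into the body frame: mid-hip at the origin, torso on +y.

    Per frame all points are translated so the mid-hip sits at the origin
    and rotated so the mid-hip -> mid-shoulder axis points along +y.  This
    cancels smooth camera rotation/translation exactly.
    """
    if traj.missing.any():
        raise ValueError("align_camera requires a complete (gap-filled) trajectory")
    midhip = _mid(traj.xy, _LHIP, _RHIP)
    midsho = _mid(traj.xy, _LSHO, _RSHO)
    v = midsho - midhip
    norm = np.linalg.norm(v, axis=1)
    if np.any(norm < 1e-12):
        raise ValueError("mid-hip and mid-shoulder coincide in at least one frame")
    c = v[:, 1] / norm  # cos
    s = v[:, 0] / norm  # sin
    rel = traj.xy - midhip[:, None, :]
    x = rel[..., 0]
    y = rel[..., 1]
    out = traj.copy()
    out.xy = np.stack(
        [c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y], axis=-1
    )
    return out


def normalise_scale(traj: VideoTrajectory) -> VideoTrajectory:
    """Scale coordinates to body-length units (median crown-to-mid-hip = 1)."""
    length = infant_length(traj)
    if length < 1e-9:
        raise ValueError("infant length is zero or near zero; cannot scale")
    out = traj.copy()
    out.xy = out.xy / length
    return out


# ---------------------------------------------------------------------------
# stage 7-10: features, band-pass, cohort outliers, downsampling

def extract_features(traj: VideoTrajectory) -> np.ndarray:
    """Flatten a complete trajectory to the t x 36 feature matrix."""
    if traj.missing.any():
        raise ValueError("feature extraction requires a complete trajectory")
    return traj.xy.reshape(traj.n_frames, -1).copy()


def bandpass_features(
    M: np.ndarray,
    fs: float = 25.0,
    band: tuple[float, float] = (0.01, 5.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per feature column.

    Equivalent to applying the order-``order`` Butterworth band-pass
    forward and backward: the realized response is the squared magnitude
    |H(f)|^2 with zero group delay, removing constant offsets and slow
    drift while attenuating high-frequency labelling jitter.

    The response is applied in the frequency domain on an odd-reflected
    (mirror) extension of the signal.  A recursive (filtfilt) realization
    is transient-dominated here: the lower band edge's settling time is
    longer than a 3-minute record, so its start-up transients would leak
    through the whole video.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band edges must satisfy 0 < {lo} < {hi} < fs/2 = {fs / 2}")
    M = np.asarray(M, float)
    T = M.shape[0]
    # odd reflection about both end values suppresses wrap-around steps
    top = 2 * M[0][None, :] - M[1 : T][::-1]
    bot = 2 * M[-1][None, :] - M[: T - 1][::-1]
    ext = np.concatenate([top, M, bot], axis=0)
    n = ext.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    b, a = signal.butter(
        order, [2 * np.pi * lo, 2 * np.pi * hi], btype="bandpass", analog=True
    )
    _, H = signal.freqs(b, a, worN=2 * np.pi * np.maximum(freqs, 1e-12))
    gain = np.abs(H) ** 2  # forward + backward pass
    gain[freqs == 0] = 0.0
    out = np.fft.irfft(np.fft.rfft(ext, axis=0) * gain[:, None], n=n, axis=0)
    return out[T - 1 : 2 * T - 1]


def compute_cohort_stats(features: list[np.ndarray]) -> CohortStats:
    """Per-feature median and SD (about the median) pooled over the cohort."""
    stacked = np.concatenate([np.asarray(f, float) for f in features], axis=0)
    med = np.median(stacked, axis=0)
    sd = np.sqrt(np.mean((stacked - med) ** 2, axis=0))
    sd = np.maximum(sd, 1e-12)
    return CohortStats(median=med, sd=sd)


def cohort_outlier_mask(
    M: np.ndarray, stats: CohortStats, k: float = 3.0
) -> np.ndarray:
    """True where a feature value sits > k cohort SDs from the cohort median."""
    M = np.asarray(M, float)
    if M.shape[1] != stats.median.shape[0]:
        raise ValueError("cohort stats do not cover all features")
    return np.abs(M - stats.median[None]) > k * stats.sd[None]


def downsample_spline(
    M: np.ndarray, mask: np.ndarray | None = None, target_len: int = 1800
) -> np.ndarray:
    """First-order spline resampling to ``target_len`` uniform samples.

    Per feature, a first-order (piecewise linear) spline is fit through the
    unmasked samples and evaluated on a uniform grid spanning the video.
    """
    M = np.asarray(M, float)
    T, D = M.shape
    if mask is None:
        mask = np.zeros_like(M, dtype=bool)
    grid = np.linspace(0.0, T - 1.0, target_len)
    out = np.empty((target_len, D))
    t = np.arange(T, dtype=float)
    for j in range(D):
        keep = ~mask[:, j]
        if keep.sum() < 2:
            raise ValueError(f"feature {j} has <2 unmasked samples; cannot resample")
        out[:, j] = np.interp(grid, t[keep], M[keep, j])
    return out


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PreprocessResult:
    pose: PoseMatrix | None
    report: QualityReport
    excluded_reason: str | None = None


def clean_trajectory(
    traj: VideoTrajectory, cfg: PreprocessConfig | None = None
) -> tuple[VideoTrajectory | None, QualityReport]:
    """Stages up to and including scaling; None if the video fails the gate."""
    cfg = cfg or PreprocessConfig()
    traj = filter_low_confidence(traj, cfg.confidence_threshold)
    report = video_quality_gate(traj, cfg.min_labelled_fraction)
    if not report.passed:
        return None, report
    mask = detect_outliers_two_step(traj, cfg)
    traj = apply_outlier_mask(traj, mask)
    traj = fill_gaps(traj, cfg.linear_gap_max, cfg.impute_max_iter)
    traj = align_camera(traj)
    traj = normalise_scale(traj)
    return traj, report


def preprocess_video(
    traj: VideoTrajectory,
    stats: CohortStats,
    cfg: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Run the full per-video pipeline given precomputed cohort statistics."""
    cfg = cfg or PreprocessConfig()
    std = _standardised(traj, cfg)
    cleaned, report = clean_trajectory(std, cfg)
    if cleaned is None:
        return PreprocessResult(None, report, excluded_reason="quality_gate")
    M = bandpass_features(extract_features(cleaned), cfg.target_fps, cfg.band, cfg.filter_order)
    mask = cohort_outlier_mask(M, stats, cfg.cohort_sd_k)
    M = downsample_spline(M, mask, cfg.downsample_len)
    return PreprocessResult(PoseMatrix(M, traj.video_id), report)


def preprocess_cohort(
    trajectories: list[VideoTrajectory], cfg: PreprocessConfig | None = None
) -> tuple[list[PreprocessResult], CohortStats]:
    """Two-pass cohort pipeline: band-passed features feed the cohort
    statistics, which then drive per-video outlier masking and downsampling."""
    cfg = cfg or PreprocessConfig()
    cleaned: list[tuple[VideoTrajectory | None, QualityReport]] = []
    feats: list[np.ndarray | None] = []
    for traj in trajectories:
        std = _standardised(traj, cfg)
        c, rep = clean_trajectory(std, cfg)
        cleaned.append((c, rep))
        if c is None:
            feats.append(None)
        else:
            feats.append(
                bandpass_features(
                    extract_features(c), cfg.target_fps, cfg.band, cfg.filter_order
                )
            )
    passing = [f for f in feats if f is not None]
    if not passing:
        raise ValueError("no videos passed the quality gate")
    stats = compute_cohort_stats(passing)
    results = []
    for traj, (c, rep), M in zip(trajectories, cleaned, feats):
        if c is None:
            results.append(PreprocessResult(None, rep, excluded_reason="quality_gate"))
            continue
        mask = cohort_outlier_mask(M, stats, cfg.cohort_sd_k)
        Md = downsample_spline(M, mask, cfg.downsample_len)
        results.append(PreprocessResult(PoseMatrix(Md, traj.video_id), rep))
    return results, stats


def _standardised(traj: VideoTrajectory, cfg: PreprocessConfig) -> VideoTrajectory:
    from .keypoint_io import standardise_frame_rate

    if traj.fps == cfg.target_fps and traj.n_frames == int(
        round(cfg.target_fps * cfg.duration_s)
    ):
        return traj
    return standardise_frame_rate(traj, cfg.target_fps, cfg.duration_s)
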