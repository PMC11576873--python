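"""Synthetic infant-movement cohorts with known ground truth.

Movement is generated in a low-dimensional latent pose space by a
ground-truth switching autoregressive process (the same model family the
analysis fits), integrated to pose weights, mapped through an orthonormal
loading matrix onto a canonical 18-point supine skeleton, and then
degraded with the nuisances of real home video: smooth camera rotation
and translation, per-frame label jitter, dropout with low confidence,
occasional gross mislabels, and a device-dependent frame rate.

Cohort covariates (corrected age 12-18 weeks, preterm status, GM class)
influence state expression through additive tilts on the log transition
probabilities into designated states, giving known effect directions that
the association stage should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arhmm
from .arhmm import ARHMMParams
from .keypoint_io import (
    BODY_POINTS,
    N_POINTS,
    CohortTable,
    VideoTrajectory,
    write_cohort_table,
    write_keypoint_table,
)

#: Canonical supine skeleton, body length 1 (crown to mid-hip), mid-hip at origin.
SKELETON: dict[str, tuple[float, float]] = {
    "crown": (0.0, 1.0),
    "left_eye": (-0.08, 0.92),
    "right_eye": (0.08, 0.92),
    "chin": (0.0, 0.82),
    "left_shoulder": (-0.18, 0.72),
    "right_shoulder": (0.18, 0.72),
    "left_elbow": (-0.30, 0.55),
    "right_elbow": (0.30, 0.55),
    "left_wrist": (-0.36, 0.38),
    "right_wrist": (0.36, 0.38),
    "left_hip": (-0.10, 0.0),
    "right_hip": (0.10, 0.0),
    "left_knee": (-0.16, -0.30),
    "right_knee": (0.16, -0.30),
    "left_heel": (-0.14, -0.62),
    "right_heel": (0.14, -0.62),
    "left_hallux": (-0.18, -0.72),
    "right_hallux": (0.18, -0.72),
}

#: Keypoints with attenuated movement (they anchor the body frame).
_ANCHOR_POINTS = ("crown", "left_hip", "right_hip", "left_shoulder", "right_shoulder")
_ANCHOR_ATTENUATION = 0.2


@dataclass
class NuisanceConfig:
    """Degradations applied when rendering a clean trajectory to 'video' pixels."""

    px_per_bodylength: float = 350.0
    image_centre: tuple[float, float] = (540.0, 960.0)
    camera_rot_walk_sd: float = 0.0015  # radians per frame (random walk)
    camera_trans_walk_sd: float = 0.4  # pixels per frame per axis
    jitter_sd: float = 1.5  # pixels, labelling noise
    dropout_prob: float = 0.03
    outlier_prob: float = 0.003
    outlier_scale: float = 1.0  # body lengths, magnitude of gross mislabels
    fps_choices: tuple[float, ...] = (15.0, 25.0, 30.0)


@dataclass
class CohortConfig:
    """Cohort composition and injected covariate effects."""

    n_participants: int = 30
    two_video_prob: float = 0.4
    age_range: tuple[float, float] = (12.0, 18.0)
    preterm_fraction: float = 0.45
    # abnormal-GM probability conditional on birth status (study-like imbalance)
    abnormal_gm_prob_preterm: float = 0.21
    abnormal_gm_prob_term: float = 0.035
    # designated states and log-scale transition tilts
    rising_state: int = 3  # entry log-odds increase with age
    falling_state: int = 1  # entry log-odds decrease with age
    preterm_states: tuple[int, ...] = (2,)
    age_effect: float = 0.15  # per centred week
    preterm_effect: float = 0.5
    gm_effect: float = 0.5  # applied to the rising state for abnormal GM
    participant_sd: float = 0.15  # random per-participant tilt on the rising state


@dataclass
class GeneratorSpec:
    """Full specification of a synthetic cohort (ground truth + nuisances)."""

    K_true: int = 4
    L_true: int = 2
    d_latent: int = 6
    truth: ARHMMParams | None = None
    loading: np.ndarray | None = None  # (36, d_latent), orthonormal columns
    weight_scale: float = 0.012  # body lengths per unit latent weight
    posture_decay: float = 0.95  # leaky integration of velocity to posture
    frame_len: int = 1800  # latent frames at 10 Hz over 180 s
    latent_fps: float = 10.0
    duration_s: float = 180.0
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.truth is None:
            self.truth = default_truth(
                self.K_true, self.L_true, self.d_latent, seed=self.master_seed
            )
        if self.loading is None:
            self.loading = default_loading(self.d_latent, seed=self.master_seed)
        rho = self.truth.companion_spectral_radius()
        if rho >= 1.0:
            raise ValueError(f"ground-truth AR dynamics unstable (radius {rho:.3f})")
        Q = self.loading.T @ self.loading
        if not np.allclose(Q, np.eye(self.d_latent), atol=1e-8):
            raise ValueError("loading columns must be orthonormal")


def default_truth(K: int = 4, L: int = 2, d: int = 6, seed: int = 0) -> ARHMMParams:
    """Construct a stable, well-separated ground-truth switching AR model.

    States differ in noise scale (rest vs vigorous movement), dynamics
    (distinct random rotations) and bias direction; self-transition
    probability ~0.88 gives dwell times of several frames at 10 Hz.
    """
    rng = np.random.default_rng(seed + 12345)
    A = np.zeros((K, L, d, d))
    sigmas = np.linspace(0.35, 1.6, K)
    mu = np.zeros((K, d))
    Sigma = np.zeros((K, d, d))
    for k in range(K):
        Qm, _ = np.linalg.qr(rng.standard_normal((d, d)))
        a = 0.45 + 0.35 * rng.random()
        A[k, 0] = a * Qm
        if L > 1:
            A[k, 1] = -0.15 * np.eye(d)
        direction = rng.standard_normal(d)
        mu[k] = 0.25 * sigmas[k] * direction / np.linalg.norm(direction)
        Sigma[k] = sigmas[k] ** 2 * np.eye(d)
    params = ARHMMParams(
        K=K, L=L, d=d, A=A, mu=mu, Sigma=Sigma,
        Phi=np.eye(K), pi0=np.full(K, 1.0 / K),
    )
    # rescale dynamics until the companion form is comfortably stable
    while params.companion_spectral_radius() > 0.95:
        params.A *= 0.9
    off = rng.dirichlet(np.ones(K - 1) * 2.0, size=K) if K > 1 else np.zeros((1, 0))
    Phi = np.empty((K, K))
    for k in range(K):
        Phi[k] = np.insert(0.12 * off[k], k, 0.88) if K > 1 else [1.0]
    pi0 = arhmm.stationary_distribution(Phi)
    params.Phi = Phi
    params.pi0 = pi0
    return params


def default_loading(d_latent: int = 6, seed: int = 0) -> np.ndarray:
    """Random orthonormal loading (36 x d_latent), attenuated on anchor points.

    Torso anchor points (crown, hips, shoulders) move much less than the
    limbs, so the camera-alignment and scaling stages retain a stable body
    frame while every pose feature still carries latent movement.
    """
    rng = np.random.default_rng(seed + 54321)
    G = rng.standard_normal((2 * N_POINTS, d_latent))
    for i, bp in enumerate(BODY_POINTS):
        if bp in _ANCHOR_POINTS:
            G[2 * i : 2 * i + 2] *= _ANCHOR_ATTENUATION
    Q, _ = np.linalg.qr(G)
    return Q[:, :d_latent]


@dataclass
class VideoGroundTruth:
    states: np.ndarray  # (1800,) latent state per 10 Hz frame
    velocity: np.ndarray  # (1799, d_latent)
    weights: np.ndarray  # (1800, d_latent)
    clean_coords: np.ndarray  # (1800, 18, 2) body-length units, canonical frame


def _tilted_transitions(
    spec: GeneratorSpec,
    age_c: float,
    preterm: bool,
    gm_abnormal: bool,
    u_participant: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply covariate tilts to the log transition probabilities."""
    c = spec.cohort
    K = spec.K_true
    tilt = np.zeros(K)
    tilt[c.rising_state] += c.age_effect * age_c + u_participant
    tilt[c.falling_state] -= c.age_effect * age_c
    if preterm:
        for s in c.preterm_states:
            tilt[s] += c.preterm_effect
    if gm_abnormal:
        tilt[c.rising_state] += c.gm_effect
    logits = np.log(np.maximum(spec.truth.Phi, 1e-12)) + tilt[None, :]
    Phi = np.exp(logits - logits.max(axis=1, keepdims=True))
    Phi /= Phi.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(Phi)):
        raise ValueError("effect sizes produced invalid transition rows")
    lp = np.log(np.maximum(spec.truth.pi0, 1e-12)) + tilt
    pi0 = np.exp(lp - lp.max())
    pi0 /= pi0.sum()
    return Phi, pi0


def simulate_video(
    spec: GeneratorSpec,
    *,
    video_id: str = "v0",
    participant_id: str = "p0",
    age: float = 15.0,
    preterm: bool = False,
    gm_abnormal: bool = False,
    u_participant: float = 0.0,
    seed: int = 0,
    nuisance: bool = True,
    fps: float | None = None,
) -> tuple[VideoTrajectory, VideoGroundTruth]:
    """Simulate one degraded keypoint video plus its latent ground truth."""
    rng = np.random.default_rng(seed)
    Phi, pi0 = _tilted_transitions(
        spec, age - 15.0, preterm, gm_abnormal, u_participant
    )
    from dataclasses import replace as _replace

    truth = _replace(spec.truth, Phi=Phi, pi0=pi0)
    vel, z = arhmm.sample(truth, spec.frame_len - 1, seed=int(rng.integers(2**31)))
    # leaky integration: posture reverts to the template over ~2 s, so the
    # infant fidgets about a baseline pose instead of drifting off camera
    weights = np.zeros((spec.frame_len, spec.d_latent))
    lam = spec.posture_decay
    for t in range(1, spec.frame_len):
        weights[t] = lam * weights[t - 1] + vel[t - 1]
    states = np.concatenate([[z[0]], z])  # state per weight frame

    template = np.array([SKELETON[bp] for bp in BODY_POINTS])
    offsets = (spec.weight_scale * weights @ spec.loading.T).reshape(
        spec.frame_len, N_POINTS, 2
    )
    clean = template[None] + offsets
    gt = VideoGroundTruth(states=states, velocity=vel, weights=weights, clean_coords=clean)

    nz = spec.nuisance
    fps = float(fps if fps is not None else nz.fps_choices[rng.integers(len(nz.fps_choices))])
    n_frames = int(round(fps * spec.duration_s))
    t_src = np.arange(spec.frame_len) / spec.latent_fps
    t_tgt = np.arange(n_frames) / fps
    coords = np.empty((n_frames, N_POINTS, 2))
    for i in range(N_POINTS):
        for j in range(2):
            coords[:, i, j] = np.interp(t_tgt, t_src, clean[:, i, j])

    if nuisance:
        theta = np.cumsum(rng.normal(0.0, nz.camera_rot_walk_sd, n_frames))
        trans = np.cumsum(
            rng.normal(0.0, nz.camera_trans_walk_sd, (n_frames, 2)), axis=0
        )
        c, s = np.cos(theta), np.sin(theta)
        x, y = coords[..., 0], coords[..., 1]
        coords = np.stack(
            [c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y],
            axis=-1,
        )
        coords = (
            nz.px_per_bodylength * coords
            + np.asarray(nz.image_centre)[None, None, :]
            + trans[:, None, :]
        )
        coords += rng.normal(0.0, nz.jitter_sd, coords.shape)
        conf = np.clip(rng.beta(8.0, 1.2, (n_frames, N_POINTS)), 0.0, 1.0)
        # gross mislabels: large displacement but confident-looking
        out_mask = rng.random((n_frames, N_POINTS)) < nz.outlier_prob
        n_out = int(out_mask.sum())
        if n_out:
            ang = rng.uniform(0, 2 * np.pi, n_out)
            mag = nz.outlier_scale * nz.px_per_bodylength * rng.uniform(0.7, 2.0, n_out)
            coords[out_mask] += np.stack([mag * np.cos(ang), mag * np.sin(ang)], axis=1)
        drop = rng.random((n_frames, N_POINTS)) < nz.dropout_prob
        coords[drop] = np.nan
        conf[drop] = np.clip(rng.beta(1.0, 12.0, int(drop.sum())), 0.0, 0.199)
    else:
        coords = nz.px_per_bodylength * coords + np.asarray(nz.image_centre)[None, None, :]
        conf = np.ones((n_frames, N_POINTS))

    traj = VideoTrajectory(
        video_id=video_id, participant_id=participant_id,
        fps=fps, xy=coords, confidence=conf,
    )
    return traj, gt


@dataclass
class SyntheticCohort:
    spec: GeneratorSpec
    trajectories: list[VideoTrajectory]
    ground_truth: list[VideoGroundTruth]
    cohort: CohortTable

    @property
    def video_ids(self) -> list[str]:
        return [t.video_id for t in self.trajectories]


def draw_covariates(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Participant/video covariate table (one row per video)."""
    c = spec.cohort
    rows = []
    for i in range(c.n_participants):
        pid = f"p{i:03d}"
        preterm = rng.random() < c.preterm_fraction
        p_ab = c.abnormal_gm_prob_preterm if preterm else c.abnormal_gm_prob_term
        gm_abn = rng.random() < p_ab
        u = rng.normal(0.0, c.participant_sd)
        n_videos = 2 if rng.random() < c.two_video_prob else 1
        lo, hi = c.age_range
        age0 = rng.uniform(lo, hi - (2.0 if n_videos == 2 else 0.0))
        ages = [age0] if n_videos == 1 else [age0, min(hi, age0 + rng.uniform(1.5, 4.0))]
        base = 100.0 - 6.0 * preterm - 10.0 * gm_abn
        for v, age in enumerate(ages):
            rows.append(
                {
                    "participant_id": pid,
                    "video_id": f"{pid}_v{v}",
                    "corrected_age": round(age, 2),
                    "birth_status": "preterm" if preterm else "term",
                    "gm_class": "abnormal_or_absent" if gm_abn else "normal",
                    "bayley_motor": round(base + rng.normal(0, 12), 1),
                    "bayley_cognitive": round(base + rng.normal(0, 12), 1),
                    "bayley_language": round(base + rng.normal(0, 12), 1),
                    "_u": u,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: GeneratorSpec, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Simulate a full cohort; optionally write keypoint CSVs + manifest."""
    rng = np.random.default_rng(spec.master_seed)
    cov = draw_covariates(spec, rng)
    trajectories = []
    truths = []
    for _, row in cov.iterrows():
        seed = int(rng.integers(2**31))
        traj, gt = simulate_video(
            spec,
            video_id=row["video_id"],
            participant_id=row["participant_id"],
            age=row["corrected_age"],
            preterm=row["birth_status"] == "preterm",
            gm_abnormal=row["gm_class"] == "abnormal_or_absent",
            u_participant=row["_u"],
            seed=seed,
        )
        trajectories.append(traj)
        truths.append(gt)
    cohort = CohortTable(cov.drop(columns=["_u"]))
    result = SyntheticCohort(spec, trajectories, truths, cohort)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for traj in trajectories:
            write_keypoint_table(traj, out / f"{traj.video_id}.csv")
        write_cohort_table(cohort, out / "cohort.csv")
        manifest = {
            "master_seed": spec.master_seed,
            "K_true": spec.K_true,
            "L_true": spec.L_true,
            "d_latent": spec.d_latent,
            "fps": {t.video_id: t.fps for t in trajectories},
            "states": {
                t.video_id: gt.states.tolist()
                for t, gt in zip(trajectories, truths)
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest))
    return result


def simulate_expression_cohort(
    spec: GeneratorSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: state chains only (no keypoint rendering).

    Returns (summaries, cohort) frames ready for the association stage,
    with per-video occupancy and bout counts computed from the latent
    ground-truth state chains.  Used for effect-recovery and type-I
    studies where rendering and decoding would only add runtime.
    """
    from dataclasses import replace as _replace

    from .state_metrics import summaries_to_frame, summarise_video

    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    cov = draw_covariates(spec, rng)
    summaries = []
    for _, row in cov.iterrows():
        Phi, pi0 = _tilted_transitions(
            spec,
            row["corrected_age"] - 15.0,
            row["birth_status"] == "preterm",
            row["gm_class"] == "abnormal_or_absent",
            row["_u"],
        )
        truth = _replace(spec.truth, Phi=Phi, pi0=pi0)
        z = arhmm.sample_states(truth, spec.frame_len, seed=int(rng.integers(2**31)))
        summaries.append(summarise_video(z, spec.K_true, row["video_id"]))
    return summaries_to_frame(summaries), cov.drop(columns=["_u"])


def make_default_fixture(seed: int = 0) -> SyntheticCohort:
    """Small deterministic cohort used by the test suite and documentation.

    30 participants, 4 latent states, lag 2, 6 latent dimensions; repeated
    calls with the same seed return identical data.
    """
    spec = GeneratorSpec(master_seed=seed)
    return simulate_cohort(spec)
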