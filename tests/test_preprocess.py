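"""Cleaning-pipeline stages: confidence filter, gate, outliers, gap fill,
camera alignment, scaling, band-pass, cohort outliers, downsampling."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from infantstates import preprocess as pp
from infantstates.keypoint_io import BODY_POINTS, N_POINTS

from conftest import skeleton_trajectory


def test_confidence_filter_threshold_is_strict():
    traj = skeleton_trajectory(n_frames=4)
    traj.confidence[0, 0] = 0.19
    traj.confidence[1, 0] = 0.2
    traj.confidence[2, 0] = 1.0
    out = pp.filter_low_confidence(traj, 0.2)
    assert out.missing[0, 0]  # strictly below -> removed
    assert not out.missing[1, 0]  # exactly at threshold -> retained
    assert not out.missing[2, 0]
    # identity on a fully confident video
    traj2 = skeleton_trajectory(n_frames=4)
    out2 = pp.filter_low_confidence(traj2, 0.2)
    np.testing.assert_array_equal(out2.xy, traj2.xy)


@pytest.mark.parametrize(
    "missing_fraction,expected_pass", [(0.31, False), (0.30, True), (0.0, True)]
)
def test_quality_gate_on_mean_labelled_fraction(missing_fraction, expected_pass):
    traj = skeleton_trajectory(n_frames=200)
    n_missing = int(round(missing_fraction * 200 * N_POINTS))
    flat = np.zeros(200 * N_POINTS, dtype=bool)
    flat[:n_missing] = True
    mask = flat.reshape(200, N_POINTS)
    traj.xy[mask] = np.nan
    report = pp.video_quality_gate(traj, 0.70)
    assert report.passed is expected_pass
    assert report.labelled_fraction == pytest.approx(1 - missing_fraction, abs=1e-9)


def test_outlier_ellipses_catch_gross_jump_only():
    traj = skeleton_trajectory(n_frames=300, jitter=0.01, seed=1)
    wrist = BODY_POINTS.index("left_wrist")
    # single-frame jump of ~6 per-axis MADs (per-point scale is 5)
    mad = np.median(np.abs(traj.xy[:, wrist, 0] - np.median(traj.xy[:, wrist, 0])))
    traj.xy[150, wrist] += 6 * mad * np.array([1.0, 1.0]) * 5 / np.sqrt(2) * 1.2
    mask = pp.detect_outliers_two_step(traj)
    assert mask[150, wrist]
    assert not mask[149, wrist] and not mask[151, wrist]
    # observation at the mid-hip centre is inside both ellipses
    chin = BODY_POINTS.index("chin")
    traj2 = skeleton_trajectory(n_frames=300, jitter=0.01, seed=2)
    lhip, rhip = BODY_POINTS.index("left_hip"), BODY_POINTS.index("right_hip")
    centre = 0.5 * (traj2.xy[:, lhip] + traj2.xy[:, rhip])
    # far-away observation: 10 body lengths from the mid-hip
    traj2.xy[10, chin] = centre[10] + np.array([10.0, 0.0])
    mask2 = pp.detect_outliers_two_step(traj2)
    assert mask2[10, chin]


def test_outlier_error_when_length_not_computable():
    traj = skeleton_trajectory(n_frames=50)
    traj.xy[:, BODY_POINTS.index("crown")] = np.nan
    with pytest.raises(ValueError, match="length"):
        pp.detect_outliers_two_step(traj)


def test_fill_gaps_linear_short_gap():
    traj = skeleton_trajectory(n_frames=30)
    j = BODY_POINTS.index("left_knee")
    traj.xy[:, j, 0] = np.arange(30, dtype=float)  # known linear signal
    traj.xy[10:13, j] = np.nan  # 3-frame gap between 9 and 13
    out = pp.fill_gaps(traj)
    np.testing.assert_allclose(out.xy[10:13, j, 0], [10.0, 11.0, 12.0], atol=1e-9)
    assert not out.missing.any()


def test_fill_gaps_identity_without_gaps():
    traj = skeleton_trajectory(n_frames=30, jitter=0.01)
    out = pp.fill_gaps(traj)
    np.testing.assert_allclose(out.xy, traj.xy, atol=1e-12)


def test_fill_gaps_multivariate_imputation_tracks_rigid_motion():
    # rigid translation: every point carries the same motion, so a long gap
    # in one coordinate is recoverable from the others
    rng = np.random.default_rng(3)
    traj = skeleton_trajectory(n_frames=600)
    drift = np.cumsum(rng.normal(0, 0.01, (600, 1, 2)), axis=0)
    traj.xy = traj.xy + drift  # rigid translation
    j = BODY_POINTS.index("right_wrist")
    truth = traj.xy[:, j, 0].copy()
    traj.xy[200:400, j] = np.nan  # 200-frame gap
    out = pp.fill_gaps(traj)
    amplitude = truth.max() - truth.min()
    err = np.abs(out.xy[200:400, j, 0] - truth[200:400]).max()
    assert err < 0.10 * amplitude


def test_fill_gaps_fully_missing_feature_raises():
    traj = skeleton_trajectory(n_frames=30)
    traj.xy[:, 4] = np.nan
    with pytest.raises(ValueError, match="missing in every frame"):
        pp.fill_gaps(traj)


def test_align_camera_inverts_constant_rotation():
    traj = skeleton_trajectory(n_frames=50, jitter=0.005, seed=4)
    canon = pp.align_camera(traj)
    th = np.deg2rad(30.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rotated = traj.copy()
    rotated.xy = traj.xy @ R.T + np.array([3.0, -2.0])
    back = pp.align_camera(rotated)
    np.testing.assert_allclose(back.xy, canon.xy, atol=1e-9)


def test_align_camera_inverts_smooth_rotation_walk():
    rng = np.random.default_rng(5)
    traj = skeleton_trajectory(n_frames=200, jitter=0.005, seed=5)
    canon = pp.align_camera(traj)
    theta = np.cumsum(rng.normal(0, 0.01, 200))
    c, s = np.cos(theta), np.sin(theta)
    x, y = traj.xy[..., 0], traj.xy[..., 1]
    moved = traj.copy()
    moved.xy = np.stack(
        [c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y], axis=-1
    ) + rng.normal(0, 1.0, (200, 1, 2))
    back = pp.align_camera(moved)
    np.testing.assert_allclose(back.xy, canon.xy, atol=1e-6)
    # idempotent: already canonical input is unchanged
    again = pp.align_camera(canon)
    np.testing.assert_allclose(again.xy, canon.xy, atol=1e-9)


def test_torso_orientation_variance_zero_after_alignment():
    traj = skeleton_trajectory(n_frames=100, jitter=0.01, seed=6)
    out = pp.align_camera(traj)
    lh, rh = BODY_POINTS.index("left_hip"), BODY_POINTS.index("right_hip")
    ls, rs = BODY_POINTS.index("left_shoulder"), BODY_POINTS.index("right_shoulder")
    midhip = 0.5 * (out.xy[:, lh] + out.xy[:, rh])
    midsho = 0.5 * (out.xy[:, ls] + out.xy[:, rs])
    v = midsho - midhip
    angles = np.arctan2(v[:, 0], v[:, 1])
    assert np.abs(angles).max() < 1e-9
    assert np.abs(midhip).max() < 1e-9


def test_normalise_scale_is_scale_invariant():
    traj = skeleton_trajectory(n_frames=50, jitter=0.01, seed=7)
    a = pp.normalise_scale(traj)
    doubled = traj.copy()
    doubled.xy = 2.0 * traj.xy
    b = pp.normalise_scale(doubled)
    np.testing.assert_allclose(a.xy, b.xy, atol=1e-12)
    assert pp.infant_length(a) == pytest.approx(1.0, abs=1e-9)


def test_bandpass_removes_dc_and_is_zero_phase():
    fs = 25.0
    t = np.arange(4500) / fs
    M = np.zeros((4500, 36))
    M[:, 0] = 5.0  # constant -> outside passband
    M[:, 1] = np.sin(2 * np.pi * 1.0 * t)  # 1 Hz -> inside passband
    out = pp.bandpass_features(M, fs=fs)
    assert np.abs(out[:, 0]).max() < 1e-6
    # zero lag: cross-correlation of input and output peaks at lag 0
    a = M[500:-500, 1]
    b = out[500:-500, 1]
    lags = sp_signal.correlation_lags(a.size, b.size)
    xc = sp_signal.correlate(a, b)
    assert lags[np.argmax(xc)] == 0


def test_bandpass_attenuates_above_passband():
    # a finite-record sine also leaks energy into the low-frequency passband,
    # so attenuation is measured on the demodulated tone amplitude, matching
    # the designed squared-magnitude response at each frequency
    fs = 25.0
    t = np.arange(4500) / fs
    M = np.zeros((4500, 36))
    M[:, 0] = np.sin(2 * np.pi * 1.0 * t)
    M[:, 1] = np.sin(2 * np.pi * 10.0 * t)
    out = pp.bandpass_features(M, fs=fs)

    def tone_amplitude(y, f):
        ph = np.exp(-2j * np.pi * f * t)
        return 2 * np.abs(np.mean(y * ph))

    ref = tone_amplitude(out[:, 0], 1.0)
    high = tone_amplitude(out[:, 1], 10.0)
    assert ref == pytest.approx(1.0, abs=0.01)
    assert high < 0.05 * ref


def test_bandpass_band_edges_validated():
    with pytest.raises(ValueError):
        pp.bandpass_features(np.zeros((100, 36)), fs=25.0, band=(0.01, 13.0))


def test_cohort_outlier_mask_threshold():
    stats = pp.CohortStats(median=np.zeros(36), sd=np.ones(36))
    M = np.zeros((5, 36))
    M[0, 0] = 3.0001
    M[1, 0] = 2.9999
    M[2, 1] = -3.0001
    mask = pp.cohort_outlier_mask(M, stats, k=3.0)
    assert mask[0, 0] and mask[2, 1]
    assert not mask[1, 0]
    assert not mask[3].any()


def test_downsample_exact_on_linear_ramp_with_mask():
    rng = np.random.default_rng(8)
    T = 4500
    M = np.tile(np.linspace(0.0, 1.0, T)[:, None], (1, 36))
    mask = rng.random((T, 36)) < 0.2
    mask[0] = mask[-1] = False
    out = pp.downsample_spline(M, mask, target_len=1800)
    expected = np.linspace(0.0, 1.0, 1800)
    for j in range(36):
        np.testing.assert_allclose(out[:, j], expected, atol=1e-12)
    assert out.shape == (1800, 36)


def test_downsample_ignores_masked_excursion():
    T = 1000
    M = np.tile(np.linspace(0.0, 1.0, T)[:, None], (1, 36))
    M[500, 0] = 100.0  # planted excursion
    mask = np.zeros_like(M, dtype=bool)
    mask[500, 0] = True
    out = pp.downsample_spline(M, mask, target_len=400)
    # oracle: plain interpolation through the unmasked samples
    t = np.arange(T, dtype=float)
    keep = np.ones(T, dtype=bool)
    keep[500] = False
    oracle = np.interp(np.linspace(0, T - 1, 400), t[keep], M[keep, 0])
    np.testing.assert_allclose(out[:, 0], oracle, atol=1e-12)
    assert np.abs(out[:, 0]).max() < 1.5


def test_downsample_too_few_samples_raises():
    M = np.zeros((10, 36))
    mask = np.ones((10, 36), dtype=bool)
    mask[0, :] = False
    with pytest.raises(ValueError, match="<2 unmasked"):
        pp.downsample_spline(M, mask, target_len=5)
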