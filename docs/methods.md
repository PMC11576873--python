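# Methods

`infantstates` models spontaneous infant movement, captured as markerless
pose-estimation keypoint trajectories, as a sequence of discrete motor
states with state-specific linear dynamics. This note records the models,
the numerical choices, and what the synthetic cohorts used for testing do
and do not establish.

## Data model and preprocessing

A video is a `frame × 18 body points × {x, y, confidence}` table (crown,
eyes, chin, shoulders, elbows, wrists, hips, knees, heels, halluces).
Videos of ~180 s arrive at device-dependent frame rates (15–31 fps) and
are linearly interpolated onto a uniform 25 fps grid (half-open
`[0, 180)` s, frame *i* at *i*/25 s → exactly 4500 frames); a resampled
frame is missing whenever either bracketing source frame is missing, so
gaps are preserved rather than bridged.

Cleaning stages, in order:

1. **Confidence filter** — observations with confidence < 0.2 are removed
   framewise (strict inequality).
2. **Quality gate** — videos with a mean labelled fraction below 70% are
   excluded and logged.
3. **Two-step ellipse outliers** — an observation is flagged if it falls
   outside (a) a whole-body ellipse centred on the per-frame mid-hip with
   semi-axes (1.5, 1.0) × infant length along/across the torso axis, or
   (b) a per-keypoint ellipse centred on the keypoint's temporal median
   with per-axis semi-axes 5 × the median absolute deviation (floored at
   10⁻³ body lengths so static points tolerate jitter). Infant length is
   the video-median crown-to-mid-hip distance. Both scales are
   configurable. Note a genuine caveat: for strongly intermittent
   movement, the MAD is set by rest periods, so a few percent of genuine
   vigorous-movement extremes can exceed 5 × MAD and be flagged; the
   defaults are a compromise between catching gross mislabels and
   preserving true extremes.
4. **Gap filling** — interior gaps strictly shorter than 5 frames are
   filled by per-coordinate linear interpolation; all remaining gaps by
   round-robin iterative multivariate imputation (all other coordinates
   as predictors, ≤ 10 rounds, imputed values clipped to the observed
   per-feature range).
5. **Camera alignment** — per frame, points are translated so the mid-hip
   is at the origin and rotated so the mid-hip → mid-shoulder axis points
   along +y. This inverts smooth camera rotation/translation exactly and
   makes the output invariant to global rigid motion of the input.
6. **Scaling** — coordinates are divided by infant length, giving
   body-length units (scale invariance).
7. **Band-pass** — each of the 36 features (18 points × x, y) is filtered
   with a zero-phase fourth-order Butterworth band-pass, 0.01–5 Hz: the
   realized response is the squared magnitude |H(f)|² (forward+backward),
   zero group delay. It is applied in the frequency domain on an
   odd-reflected extension of the signal rather than recursively: the
   0.01 Hz corner has a ~100 s settling time, longer than the record
   itself, so any filtfilt-style realization is dominated by start-up
   transients. Note that a *finite-record* tone leaks energy into the
   0.01–0.1 Hz passband (∝ 1/(πfT)); attenuation statements therefore
   refer to the demodulated tone amplitude, which matches the designed
   response (≈10⁻⁵ at 10 Hz).
8. **Cohort outliers** — with per-feature medians and SDs pooled over all
   gate-passing videos (two-pass design; stats are persisted so single
   videos can be reprocessed deterministically), samples more than 3 SD
   from the cohort median are masked.
9. **Downsampling** — each feature is resampled to 1800 frames (10 Hz) by
   a first-order spline through the unmasked samples.

The result is an 1800 × 36 pose matrix per video with no missing values.

## Principal movements

Per video, features are demeaned and scaled to unit SD (per video, so
residual position/size differences cancel), concatenated along time over
a random one-video-per-participant subset (default 100 videos), and
decomposed by SVD, `M = U S Vᵀ`. Columns of `V` are pose eigenvectors —
coordinated whole-body movement patterns — and the weights `U S` measure
posture deviation from the mean pose along each eigenvector. Sign
ambiguity is resolved by making each eigenvector's largest-magnitude
element positive. New videos are normalised the same way and projected
onto the first *k* eigenvectors (default k = 15); the modelled signal is
the first difference of the weights (velocity, units weight/frame at
10 Hz; the constant Δt is absorbed by the dynamics). Differencing happens
after truncation to *k* components.

## Autoregressive hidden Markov model

Observations follow, for hidden state *k* and lag order *L*,

    x_t | x_{t-1..t-L}, z_t = k  ~  N( Σ_l A_k^l x_{t-l} + μ_k , S_k )

with a K × K transition matrix Φ and an initial distribution π₀
(estimated; needed for a proper likelihood over many sequences). L = 0
gives a Gaussian HMM; tying all rows of Φ to the mixture weights removes
temporal structure entirely and reduces the EM exactly to Gaussian
mixture fitting — all three model classes share one implementation.
K = 1 is a plain vector AR model.

Likelihoods condition on the first L observations of each sequence (no
marginalisation of initial lags), the standard choice for switching AR
models; it affects all model comparisons equally. Recursions run in
log space (numba-compiled forward, forward–backward and Viterbi; ties in
argmax break toward the lower state index). Decoded labels for the first
L frames inherit the first decodable frame's label.

**EM.** E-step: forward–backward posteriors per sequence. M-step:
per-state weighted least squares for (A_k, μ_k) (with a ~10⁻⁸-scale ridge
for conditioning), weighted residual covariance for S_k (symmetrised,
diagonal floored at 10⁻⁶, positive-definiteness enforced), normalised
expected transition/initial counts for Φ and π₀. Initialisation: k-means
on lag-stacked windows `[x_t, x_{t-1..t-L}]` seeds hard assignments, from
which one M-step produces the starting parameters. Convergence uses the
relative log-likelihood change; the default tolerance is 10⁻⁶ — a looser
tolerance measurably underfits (each EM iteration near convergence still
gains several nats on 10⁵-frame problems), which distorts model
comparison. Full-batch EM has a non-decreasing likelihood trace; the
stochastic variant makes one randomly ordered pass over sequences per
iteration, blending sufficient statistics with decay 0.75 and re-solving
the M-step after each sequence, and reaches within ~0.1% of the
full-batch likelihood on recovery problems.

**Model selection.** Videos (never frames) are split into 5
cross-validation folds, optionally at the participant level. Each grid
cell (class, K, L) is scored by mean per-frame held-out log-likelihood
and by AIC with

    p = K (L d² + d + d(d+1)/2) + K(K−1) + (K−1).

Both criteria are reported; the default selection rule is held-out
likelihood, ties breaking toward smaller K then smaller L. On synthetic
data the held-out curve saturates near the true state count (gains beyond
it are marginal), and both rules recover the true (K, L) reliably when
fits are run to convergence.

**Final fit.** The chosen model is refit `repeats` times (default 25)
from independent seeds; runs are aligned to the highest-likelihood run by
Hungarian assignment on per-state blocks `[vec(A_k), μ_k, vech(S_k)]`
(label switching makes naive averaging meaningless), then averaged
element-wise; Φ rows and π₀ are renormalised and the averaged covariances
checked for positive definiteness.

## State metrics

From decoded labels: occupancy (fraction of frames per state), bout
counts (maximal runs, configurable minimum length), dwell statistics
(median run length pooled across states over runs ≥ 2 frames — matching
the convention of reporting a single pooled median — and the longest run
per video). High-velocity specificity: per body point, frames above the
cohort-pooled 90th percentile of frame-to-frame displacement (computed on
cleaned body-length coordinates at 10 Hz) are tagged and attributed to
their decoded state, then aggregated within three clusters — arms
(shoulders, elbows, wrists), legs (hips, knees, heels, halluces), head
(crown, chin, eyes). Pooling the threshold across the cohort keeps videos
comparable on a common scale. A seeded uniform sampler provides per-state
displacement vectors for visualisation.

## Association

Per state, a linear mixed model regresses occupancy or bout count on
fixed effects (corrected age centred at 15 weeks, preterm birth, GM
classification, Bayley-III composites) with a participant random
intercept, fit by REML; Wald p-values. Where a participant has two
videos, the later video's GM classification applies (outcome assessed at
the later timepoint). Singular fits (zero random-effect variance) fall
back to OLS with cluster-robust standard errors. Significance uses
Bonferroni over the K states (α/K with α = 0.05).

## Synthetic cohorts

The generator mirrors the analysis's own representation so recovery is
well-posed: a ground-truth ARHMM (default K = 4, L = 2, d = 6) generates
latent velocity at 10 Hz; velocity integrates *leakily* into pose weights
(decay 0.95 per frame, ~2 s reversion) so the infant fidgets about a
baseline posture instead of drifting off camera; weights map through an
orthonormal loading matrix onto a canonical supine 18-point skeleton
(body length 1). Torso anchors (crown, hips, shoulders) move with 0.2×
attenuation — enough to keep every feature informative (a perfectly rigid
anchor would be amplified to pure unit-variance noise by the per-video
normalisation) while preserving a stable body frame for alignment.

The rendered video then receives the nuisances of home smartphone video:
camera rotation and translation random walks, ~1.5 px labelling jitter,
3% dropout (missing, confidence < 0.2), 0.3% gross mislabels, pixel
scaling/offset, and a device frame rate drawn from {15, 25, 30} fps.
Ground-truth states, weights and clean coordinates are returned alongside.

Cohort covariates (age 12–18 weeks, ~45% preterm, abnormal-GM probability
higher among preterm) influence expression through additive tilts on the
log transition probabilities into designated states: one state's entry
odds rise with age, another's fall, preterm status tilts a third; a small
per-participant random tilt creates genuine repeated-measures
correlation. All randomness flows from one master seed through per-video
derived seeds (bit-reproducible cohorts).

What passing tests show — and don't: the synthetic cohort has exactly the
model's generative structure (plus controlled nuisance), so recovery
results demonstrate correctness of the estimation machinery, not that
real infant movement is a switching AR process; real pose data add model
misfit, occlusion structure, and labelling errors correlated with pose
that the generator does not emulate.

## Problem sizes

The default test fixture uses 30 participants (~42 videos), chosen so the
full simulate → preprocess → project → fit → decode loop completes in a
few minutes while leaving comfortable margins on the recovery properties
(end-to-end state accuracy ~0.90 at the default k = 15 against a 0.85
bar). Selection and ordering experiments run on 15–20 sequences of
500–900 frames; association calibration uses 100 replicate cohorts on
ground-truth state chains (isolating the association stage; the
rendering-and-decoding half of the loop is covered by the end-to-end
test).

## Known limitations

2-D image-plane geometry only (no joint angles or 3-D kinematics); the
ellipse outlier stage can clip genuine movement extremes (see above);
mapping of states to clinical movement categories is out of scope; the
generator's covariate effects act on transitions only, so emission-level
group differences are untested.
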