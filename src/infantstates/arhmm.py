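"""Autoregressive hidden Markov models over movement-velocity series.

The observation model for hidden state k with lag order L is

    x_t | x_{t-1..t-L}, z_t = k  ~  N( sum_l A_k^l x_{t-l} + mu_k , S_k )

Special cases: L = 0 gives a Gaussian HMM; additionally tying all
transition rows to the stationary weights gives a Gaussian mixture with
no temporal structure; K = 1 is a plain vector AR model.

Fitting is expectation-maximisation: forward-backward posteriors in the
E-step, closed-form weighted least squares (dynamics and bias), weighted
covariances and normalised expected counts in the M-step.  Likelihoods
condition on the first L observations of every sequence, so the hidden
chain runs over frames L..T-1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg

from ._recursions import forward_backward, forward_loglik, viterbi_path

_LOG2PI = np.log(2.0 * np.pi)
_COV_FLOOR = 1e-6


@dataclass
class ARHMMParams:
    """Parameters of a K-state, lag-L autoregressive HMM in d dimensions."""

    K: int
    L: int
    d: int
    A: np.ndarray  # (K, L, d, d)
    mu: np.ndarray  # (K, d)
    Sigma: np.ndarray  # (K, d, d)
    Phi: np.ndarray  # (K, K) transition matrix, rows sum to 1
    pi0: np.ndarray  # (K,) initial state distribution
    tied_transitions: bool = False  # True => mixture model (no state memory)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float).reshape(self.K, self.L, self.d, self.d)
        self.mu = np.asarray(self.mu, float).reshape(self.K, self.d)
        self.Sigma = np.asarray(self.Sigma, float).reshape(self.K, self.d, self.d)
        self.Phi = np.asarray(self.Phi, float).reshape(self.K, self.K)
        self.pi0 = np.asarray(self.pi0, float).reshape(self.K)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if np.any(self.Phi < -1e-12) or not np.allclose(self.Phi.sum(1), 1, atol=1e-8):
            raise ValueError("rows of Phi must be non-negative and sum to 1")
        if not np.allclose(self.pi0.sum(), 1, atol=1e-8) or np.any(self.pi0 < -1e-12):
            raise ValueError("pi0 must be a probability distribution")
        for k in range(self.K):
            if not np.allclose(self.Sigma[k], self.Sigma[k].T, atol=1e-8):
                raise ValueError(f"Sigma[{k}] must be symmetric")

    # -- packed regression weights: mean_t = [x_{t-1},..,x_{t-L},1] @ W_k ----
    def _weights(self) -> np.ndarray:
        K, L, d = self.K, self.L, self.d
        W = np.empty((K, L * d + 1, d))
        for k in range(K):
            for l in range(L):
                W[k, l * d : (l + 1) * d] = self.A[k, l].T
            W[k, -1] = self.mu[k]
        return W

    def n_parameters(self) -> int:
        """Free-parameter count used for AIC."""
        K, L, d = self.K, self.L, self.d
        return K * (L * d * d + d + d * (d + 1) // 2) + K * (K - 1) + (K - 1)

    def companion_spectral_radius(self) -> float:
        """Largest spectral radius of the per-state companion matrices."""
        K, L, d = self.K, self.L, self.d
        if L == 0:
            return 0.0
        worst = 0.0
        for k in range(K):
            C = np.zeros((L * d, L * d))
            for l in range(L):
                C[:d, l * d : (l + 1) * d] = self.A[k, l]
            if L > 1:
                C[d:, :-d] = np.eye((L - 1) * d)
            worst = max(worst, float(np.abs(np.linalg.eigvals(C)).max()))
        return worst

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "schema": "infantstates.arhmm.v1",
            "K": self.K,
            "L": self.L,
            "d": self.d,
            "A": self.A.tolist(),
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "Phi": self.Phi.tolist(),
            "pi0": self.pi0.tolist(),
            "tied_transitions": self.tied_transitions,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ARHMMParams":
        p = json.loads(Path(path).read_text())
        return cls(
            K=p["K"], L=p["L"], d=p["d"],
            A=np.array(p["A"]), mu=np.array(p["mu"]), Sigma=np.array(p["Sigma"]),
            Phi=np.array(p["Phi"]), pi0=np.array(p["pi0"]),
            tied_transitions=p.get("tied_transitions", False),
        )


@dataclass
class StateSequence:
    """Decoded per-frame labels and posterior marginals for one video."""

    labels: np.ndarray  # (T,) ints in 0..K-1
    posterior: np.ndarray  # (T, K), rows sum to 1
    video_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.posterior = np.asarray(self.posterior, float)


@dataclass
class FitResult:
    params: ARHMMParams
    loglik_trace: np.ndarray
    converged: bool
    seed: int
    n_iterations: int


# ---------------------------------------------------------------------------
# emission densities

def _design(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix Z (T-L, L*d+1) and response Y (T-L, d)."""
    x = np.asarray(x, float)
    T, d = x.shape
    if T <= L:
        raise ValueError(f"sequence length {T} must exceed lag {L}")
    Z = np.empty((T - L, L * d + 1))
    for l in range(1, L + 1):
        Z[:, (l - 1) * d : l * d] = x[L - l : T - l]
    Z[:, -1] = 1.0
    return Z, x[L:]


def _emission_logdensities(params: ARHMMParams, x: np.ndarray) -> np.ndarray:
    """(T-L, K) per-frame, per-state Gaussian AR log-densities."""
    if not np.all(np.isfinite(x)):
        raise ValueError("observations must be finite")
    Z, Y = _design(x, params.L)
    W = params._weights()
    Tm, K, d = Y.shape[0], params.K, params.d
    out = np.empty((Tm, K))
    for k in range(K):
        resid = Y - Z @ W[k]
        try:
            c, low = linalg.cho_factor(params.Sigma[k], lower=True)
        except linalg.LinAlgError:
            c, low = linalg.cho_factor(
                params.Sigma[k] + _COV_FLOOR * np.eye(d), lower=True
            )
        sol = linalg.cho_solve((c, low), resid.T)
        quad = np.einsum("dt,dt->t", resid.T, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        out[:, k] = -0.5 * (quad + d * _LOG2PI + logdet)
    return out


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(p, 1e-300))


# ---------------------------------------------------------------------------
# likelihood / decoding / sampling

def log_likelihood(params: ARHMMParams, sequences: list[np.ndarray]) -> float:
    """Total marginal log p(x) over sequences (conditioning on first L frames)."""
    total = 0.0
    lphi = _safe_log(params.Phi)
    lpi = _safe_log(params.pi0)
    for x in sequences:
        logb = _emission_logdensities(params, x)
        if params.tied_transitions:
            lw = _safe_log(params.pi0)
            total += float(
                np.sum(_logsumexp_rows(logb + lw[None, :]))
            )
        else:
            total += float(forward_loglik(lpi, lphi, logb))
    return total


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True)))[:, 0]


def posterior_decode(
    params: ARHMMParams, sequence: np.ndarray, video_id: str = ""
) -> StateSequence:
    """Forward-backward posterior marginals; labels are row argmaxes.

    The first L frames (which only condition the AR emissions) inherit
    the first decodable frame's posterior and label.
    """
    x = np.asarray(sequence, float)
    if x.shape[0] < params.L + 1:
        raise ValueError("sequence shorter than L+1 frames")
    logb = _emission_logdensities(params, x)
    if params.tied_transitions:
        lw = _safe_log(params.pi0)
        g = logb + lw[None, :]
        g = np.exp(g - g.max(axis=1, keepdims=True))
        gamma = g / g.sum(axis=1, keepdims=True)
    else:
        _, gamma, _, _ = forward_backward(
            _safe_log(params.pi0), _safe_log(params.Phi), logb
        )
    T = x.shape[0]
    post = np.empty((T, params.K))
    post[params.L :] = gamma
    post[: params.L] = gamma[0]
    labels = np.argmax(post, axis=1)
    return StateSequence(labels=labels, posterior=post, video_id=video_id)


def viterbi(params: ARHMMParams, sequence: np.ndarray) -> np.ndarray:
    """Maximum a posteriori joint state path (ties -> lower state index)."""
    x = np.asarray(sequence, float)
    if x.shape[0] < params.L + 1:
        raise ValueError("sequence shorter than L+1 frames")
    logb = _emission_logdensities(params, x)
    path = viterbi_path(_safe_log(params.pi0), _safe_log(params.Phi), logb)
    return np.concatenate([np.full(params.L, path[0]), path])


def sample(
    params: ARHMMParams,
    T: int,
    seed: int = 0,
    x_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a synthetic sequence (observations, states) of length T.

    States follow pi0/Phi; observations follow the per-state AR Gaussian
    given the last L samples.  When ``x_init`` is omitted the first L
    frames are drawn from the state's unconditional bias N(mu_k, S_k).
    """
    K, L, d = params.K, params.L, params.d
    if T <= L:
        raise ValueError("T must exceed L")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(params.Sigma)
    z = np.empty(T, dtype=int)
    x = np.empty((T, d))
    z[0] = rng.choice(K, p=params.pi0)
    for t in range(1, T):
        if params.tied_transitions:
            z[t] = rng.choice(K, p=params.pi0)
        else:
            z[t] = rng.choice(K, p=params.Phi[z[t - 1]])
    if x_init is not None:
        x[:L] = np.asarray(x_init, float).reshape(L, d)
    else:
        for t in range(L):
            x[t] = params.mu[z[t]] + chol[z[t]] @ rng.standard_normal(d)
    for t in range(L, T):
        k = z[t]
        mean = params.mu[k].copy()
        for l in range(1, L + 1):
            mean += params.A[k, l - 1] @ x[t - l]
        x[t] = mean + chol[k] @ rng.standard_normal(d)
        if np.abs(x[t]).max() > 1e8:
            raise FloatingPointError(
                "sample overflow: AR dynamics appear unstable "
                "(check companion_spectral_radius() < 1)"
            )
    return x, z


def sample_states(params: ARHMMParams, T: int, seed: int = 0) -> np.ndarray:
    """Draw only a hidden-state chain of length T (fast path)."""
    rng = np.random.default_rng(seed)
    K = params.K
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(K, p=params.pi0)
    # vectorised chain sampling via per-row inverse CDF
    cdf = np.cumsum(params.Phi, axis=1)
    u = rng.random(T)
    for t in range(1, T):
        z[t] = np.searchsorted(cdf[z[t - 1]], u[t])
    return z


def stationary_distribution(Phi: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(Phi.T)
    i = int(np.argmin(np.abs(vals - 1)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def aic(fit: FitResult, data: list[np.ndarray]) -> float:
    """Akaike information criterion 2p - 2 log L on the given data."""
    p = fit.params.n_parameters()
    return 2.0 * p - 2.0 * log_likelihood(fit.params, data)


# ---------------------------------------------------------------------------
# EM fitting

def _init_params(
    sequences: list[np.ndarray],
    K: int,
    L: int,
    seed: int,
    tied: bool,
) -> ARHMMParams:
    """K-means on lag-stacked windows seeds states; per-cluster regression."""
    d = sequences[0].shape[1]
    designs = [_design(x, L) for x in sequences]
    windows = np.concatenate([np.hstack([Y, Z[:, : L * d]]) for Z, Y in designs])
    rng = np.random.default_rng(seed)
    if windows.shape[0] > 20000:
        sub = rng.choice(windows.shape[0], 20000, replace=False)
        fit_windows = windows[sub]
    else:
        fit_windows = windows
    if K == 1:
        labels_all = [np.zeros(Y.shape[0], dtype=int) for _, Y in designs]
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=3, random_state=int(seed) % (2**31)).fit(
            fit_windows
        )
        labels_all = []
        start = 0
        lab = km.predict(windows)
        for _, Y in designs:
            labels_all.append(lab[start : start + Y.shape[0]])
            start += Y.shape[0]
    # hard-assignment M-step as the starting point
    gammas = []
    for lab in labels_all:
        g = np.zeros((lab.shape[0], K))
        g[np.arange(lab.shape[0]), lab] = 1.0
        gammas.append(g)
    trans = np.ones((K, K))
    init = np.ones(K)
    for lab in labels_all:
        np.add.at(trans, (lab[:-1], lab[1:]), 1.0)
        init[lab[0]] += 1.0
    A, mu, Sigma = _mstep_emissions(designs, gammas, K, L, d)
    Phi = trans / trans.sum(axis=1, keepdims=True)
    pi0 = init / init.sum()
    if tied:
        w = np.concatenate(gammas).mean(axis=0)
        w = w / w.sum()
        Phi = np.tile(w, (K, 1))
        pi0 = w
    return ARHMMParams(K=K, L=L, d=d, A=A, mu=mu, Sigma=Sigma, Phi=Phi, pi0=pi0,
                       tied_transitions=tied)


def _mstep_emissions(designs, gammas, K, L, d):
    p = L * d + 1
    A = np.empty((K, L, d, d))
    mu = np.empty((K, d))
    Sigma = np.empty((K, d, d))
    for k in range(K):
        Sw = np.zeros((p, p))
        Sy = np.zeros((p, d))
        Syy = np.zeros((d, d))
        Nk = 0.0
        for (Z, Y), g in zip(designs, gammas):
            gk = g[:, k]
            Zw = Z * gk[:, None]
            Sw += Z.T @ Zw
            Sy += Zw.T @ Y
            Syy += (Y * gk[:, None]).T @ Y
            Nk += gk.sum()
        ridge = 1e-8 * (np.trace(Sw) / p + 1.0)
        W = np.linalg.solve(Sw + ridge * np.eye(p), Sy)
        Nk = max(Nk, 1e-12)
        S = (Syy - W.T @ Sy - Sy.T @ W + W.T @ Sw @ W) / Nk
        S = 0.5 * (S + S.T)
        dd = np.diag(S).copy()
        np.fill_diagonal(S, np.maximum(dd, _COV_FLOOR))
        # guard positive definiteness
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            warnings.warn("degenerate covariance; ridge-regularising", RuntimeWarning)
            S += (1e-6 + 1e-6 * np.trace(S) / d) * np.eye(d)
        for l in range(L):
            A[k, l] = W[l * d : (l + 1) * d].T
        mu[k] = W[-1]
        Sigma[k] = S
    return A, mu, Sigma


def _estep(params: ARHMMParams, designs, xs):
    """Posteriors and sufficient stats for every sequence; returns loglik."""
    lphi = _safe_log(params.Phi)
    lpi = _safe_log(params.pi0)
    gammas = []
    xi_tot = np.zeros((params.K, params.K))
    pi_tot = np.zeros(params.K)
    ll = 0.0
    for x in xs:
        logb = _emission_logdensities(params, x)
        if params.tied_transitions:
            lw = _safe_log(params.pi0)
            a = logb + lw[None, :]
            ll += float(np.sum(_logsumexp_rows(a)))
            g = np.exp(a - a.max(axis=1, keepdims=True))
            g /= g.sum(axis=1, keepdims=True)
            gammas.append(g)
            pi_tot += g.sum(axis=0)
        else:
            l, g, xi, g0 = forward_backward(lpi, lphi, logb)
            ll += float(l)
            gammas.append(g)
            xi_tot += xi
            pi_tot += g0
    return ll, gammas, xi_tot, pi_tot


def fit_em(
    sequences: list[np.ndarray],
    K: int,
    L: int,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    mode: str = "full",
    tied_transitions: bool = False,
    verbose: bool = False,
) -> FitResult:
    """Fit an ARHMM (or HMM with L=0, mixture with tied transitions) by EM.

    ``mode='full'`` is full-batch EM with a non-decreasing log-likelihood
    trace; ``mode='stochastic'`` makes one randomly ordered pass over the
    sequences per iteration, blending sufficient statistics with decay
    0.75 and re-solving the M-step after each sequence.
    """
    if K < 1 or L < 0:
        raise ValueError("require K >= 1 and L >= 0")
    xs = [np.asarray(x, float) for x in sequences]
    if not xs:
        raise ValueError("at least one sequence required")
    for x in xs:
        if not np.all(np.isfinite(x)):
            raise ValueError("observations must be finite")
    d = xs[0].shape[1]
    n_frames = sum(x.shape[0] - L for x in xs)
    n_par = K * (L * d * d + d + d * (d + 1) // 2) + K * K
    if n_frames < 3 * n_par:
        warnings.warn(
            f"only {n_frames} usable frames for ~{n_par} parameters", RuntimeWarning
        )
    designs = [_design(x, L) for x in xs]
    params = _init_params(xs, K, L, seed, tied_transitions)

    trace: list[float] = []
    converged = False
    if mode == "full":
        for it in range(max_iter):
            ll, gammas, xi, pi = _estep(params, designs, xs)
            trace.append(ll)
            if len(trace) > 1:
                denom = abs(trace[-2]) + 1e-12
                if (trace[-1] - trace[-2]) / denom < tol:
                    converged = True
                    break
            params = _mstep(params, designs, gammas, xi, pi, tied_transitions)
    elif mode == "stochastic":
        rng = np.random.default_rng(seed)
        decay = 0.75
        n = len(xs)
        stats = None
        for it in range(max_iter):
            order = rng.permutation(n)
            ll_pass = 0.0
            for i in order:
                l, g, xi_i, pi_i = _estep(params, [designs[i]], [xs[i]])
                ll_pass += l
                seq_stats = _collect_stats([designs[i]], [g[0]], xi_i, pi_i, K, L, d)
                scaled = tuple(n * s for s in seq_stats)
                if stats is None:
                    stats = scaled
                else:
                    stats = tuple(
                        decay * old + (1 - decay) * new
                        for old, new in zip(stats, scaled)
                    )
                params = _mstep_from_stats(params, stats, tied_transitions)
            trace.append(ll_pass)
            if len(trace) > 1:
                denom = abs(trace[-2]) + 1e-12
                if abs(trace[-1] - trace[-2]) / denom < tol:
                    converged = True
                    break
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not trace:
        trace = [log_likelihood(params, xs)]
    return FitResult(
        params=params,
        loglik_trace=np.array(trace),
        converged=converged,
        seed=seed,
        n_iterations=len(trace),
    )


def _collect_stats(designs, gammas, xi, pi, K, L, d):
    p = L * d + 1
    Sw = np.zeros((K, p, p))
    Sy = np.zeros((K, p, d))
    Syy = np.zeros((K, d, d))
    Nk = np.zeros(K)
    for (Z, Y), g in zip(designs, gammas):
        for k in range(K):
            gk = g[:, k]
            Zw = Z * gk[:, None]
            Sw[k] += Z.T @ Zw
            Sy[k] += Zw.T @ Y
            Syy[k] += (Y * gk[:, None]).T @ Y
            Nk[k] += gk.sum()
    return Sw, Sy, Syy, Nk, xi.copy(), pi.copy()


def _mstep_from_stats(params: ARHMMParams, stats, tied: bool) -> ARHMMParams:
    Sw, Sy, Syy, Nk, xi, pi = stats
    K, L, d = params.K, params.L, params.d
    p = L * d + 1
    A = np.empty((K, L, d, d))
    mu = np.empty((K, d))
    Sigma = np.empty((K, d, d))
    for k in range(K):
        ridge = 1e-8 * (np.trace(Sw[k]) / p + 1.0)
        W = np.linalg.solve(Sw[k] + ridge * np.eye(p), Sy[k])
        n = max(Nk[k], 1e-12)
        S = (Syy[k] - W.T @ Sy[k] - Sy[k].T @ W + W.T @ Sw[k] @ W) / n
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, np.maximum(np.diag(S), _COV_FLOOR))
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            warnings.warn("degenerate covariance; ridge-regularising", RuntimeWarning)
            S += (1e-6 + 1e-6 * np.trace(S) / d) * np.eye(d)
        for l in range(L):
            A[k, l] = W[l * d : (l + 1) * d].T
        mu[k] = W[-1]
        Sigma[k] = S
    if tied:
        w = Nk / Nk.sum()
        Phi = np.tile(w, (K, 1))
        pi0 = w
    else:
        row = xi.sum(axis=1, keepdims=True)
        Phi = np.where(row > 0, xi / np.maximum(row, 1e-300), 1.0 / K)
        Phi = Phi / Phi.sum(axis=1, keepdims=True)
        tot = pi.sum()
        pi0 = pi / tot if tot > 0 else np.full(K, 1.0 / K)
    return replace(params, A=A, mu=mu, Sigma=Sigma, Phi=Phi, pi0=pi0)


def _mstep(params, designs, gammas, xi, pi, tied) -> ARHMMParams:
    K, L, d = params.K, params.L, params.d
    stats = _collect_stats(designs, gammas, xi, pi, K, L, d)
    return _mstep_from_stats(params, stats, tied)
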