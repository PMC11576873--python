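"""ARHMM core: likelihood against enumeration, EM monotonicity and
recovery, decoding, Viterbi against brute force, sampling moments."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from infantstates import arhmm
from infantstates.arhmm import ARHMMParams
from infantstates.model_selection import (
    align_params,
    best_label_permutation,
    permute_states,
)
from infantstates.synthetic import default_truth


def random_params(K, L, d, rng, tied=False):
    A = rng.normal(0, 0.3 / max(L, 1), (K, L, d, d)) if L else np.zeros((K, 0, d, d))
    mu = rng.normal(0, 1.0, (K, d))
    Sigma = np.empty((K, d, d))
    for k in range(K):
        W = rng.normal(0, 1.0, (d, d + 2))
        Sigma[k] = W @ W.T / (d + 2) + 0.3 * np.eye(d)
    Phi = rng.dirichlet(np.ones(K) * 2, size=K)
    pi0 = rng.dirichlet(np.ones(K))
    if tied:
        Phi = np.tile(pi0, (K, 1))
    return ARHMMParams(K=K, L=L, d=d, A=A, mu=mu, Sigma=Sigma, Phi=Phi, pi0=pi0,
                       tied_transitions=tied)


def enumeration_loglik(params, x):
    """Independent oracle: log-sum over all K^(T-L) state paths."""
    from itertools import product
    from scipy.special import logsumexp

    T, d = x.shape
    K, L = params.K, params.L
    n = T - L
    terms = []
    for path in product(range(K), repeat=n):
        lp = np.log(params.pi0[path[0]])
        for a, b in zip(path[:-1], path[1:]):
            lp += np.log(params.Phi[a, b])
        for i, k in enumerate(path):
            t = L + i
            mean = params.mu[k].copy()
            for l in range(1, L + 1):
                mean = mean + params.A[k, l - 1] @ x[t - l]
            lp += multivariate_normal.logpdf(x[t], mean, params.Sigma[k])
        terms.append(lp)
    return logsumexp(terms)


def test_forward_matches_enumeration_on_many_random_instances():
    rng = np.random.default_rng(0)
    worst = 0.0
    for trial in range(100):
        K = int(rng.integers(1, 4))
        L = int(rng.integers(0, 3))
        d = int(rng.integers(1, 4))
        T = int(rng.integers(L + 2, 9))
        params = random_params(K, L, d, rng)
        x = rng.normal(0, 1.0, (T, d))
        got = arhmm.log_likelihood(params, [x])
        want = enumeration_loglik(params, x)
        worst = max(worst, abs(got - want))
    assert worst < 1e-8


def test_likelihood_reduces_to_gaussian_for_single_state():
    rng = np.random.default_rng(1)
    params = random_params(1, 0, 3, rng)
    x = rng.normal(0, 1, (50, 3))
    want = multivariate_normal.logpdf(x, params.mu[0], params.Sigma[0]).sum()
    assert arhmm.log_likelihood(params, [x]) == pytest.approx(want, abs=1e-8)


def test_absorbing_chain_equals_single_state_likelihood():
    rng = np.random.default_rng(2)
    p2 = random_params(2, 1, 2, rng)
    p2.Phi = np.eye(2)
    p2.pi0 = np.array([1.0, 0.0])
    p1 = ARHMMParams(
        K=1, L=1, d=2, A=p2.A[:1], mu=p2.mu[:1], Sigma=p2.Sigma[:1],
        Phi=np.ones((1, 1)), pi0=np.ones(1),
    )
    x = rng.normal(0, 1, (40, 2))
    assert arhmm.log_likelihood(p2, [x]) == pytest.approx(
        arhmm.log_likelihood(p1, [x]), abs=1e-8
    )


def test_em_loglik_trace_nondecreasing():
    rng = np.random.default_rng(3)
    truth = default_truth(K=2, L=1, d=3, seed=3)
    xs = [arhmm.sample(truth, 400, seed=i)[0] for i in range(4)]
    fit = arhmm.fit_em(xs, K=2, L=1, max_iter=60, tol=0.0, seed=0)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8 * np.abs(fit.loglik_trace[:-1]))


def test_single_state_ar_fit_matches_least_squares():
    rng = np.random.default_rng(4)
    d = 3
    T = 12_000  # coefficient standard error ~0.008, well inside the 0.02 band
    x = np.zeros((T, d))
    for t in range(1, T):
        x[t] = 0.5 * x[t - 1] + rng.normal(0, 1.0, d)
    fit = arhmm.fit_em([x], K=1, L=1, max_iter=5, tol=1e-10, seed=0)
    # ordinary least squares oracle on the same data
    Z = np.hstack([x[:-1], np.ones((T - 1, 1))])
    W, *_ = np.linalg.lstsq(Z, x[1:], rcond=None)
    A_ols = W[:d].T
    np.testing.assert_allclose(fit.params.A[0, 0], A_ols, atol=1e-6)
    np.testing.assert_allclose(fit.params.A[0, 0], 0.5 * np.eye(d), atol=0.02)


def test_parameter_recovery(recovery_truth, recovery_data, recovery_fit):
    xs, zs = recovery_data
    perm = align_params(recovery_truth, recovery_fit.params)
    aligned = permute_states(recovery_fit.params, perm)
    assert np.abs(aligned.Phi - recovery_truth.Phi).max() < 0.05
    tt = np.concatenate(zs)
    pred = np.concatenate(
        [arhmm.posterior_decode(recovery_fit.params, x).labels for x in xs]
    )
    pl = best_label_permutation(tt, pred, 3)
    assert np.mean(pl[pred] == tt) > 0.90


def test_stochastic_em_close_to_full_batch(recovery_data):
    xs, _ = recovery_data
    sub = xs[:8]
    full = arhmm.fit_em(sub, K=3, L=2, max_iter=100, tol=1e-6, seed=0, mode="full")
    sto = arhmm.fit_em(sub, K=3, L=2, max_iter=40, tol=1e-6, seed=0, mode="stochastic")
    ll_full = arhmm.log_likelihood(full.params, sub)
    ll_sto = arhmm.log_likelihood(sto.params, sub)
    assert abs(ll_sto - ll_full) / abs(ll_full) < 0.01


def test_posterior_decode_properties():
    rng = np.random.default_rng(5)
    # well-separated two-state mixture: emission means far apart
    params = random_params(2, 0, 2, rng)
    params.mu = np.array([[-10.0, -10.0], [10.0, 10.0]])
    params.Sigma = np.stack([np.eye(2), np.eye(2)])
    params.Phi = np.array([[0.95, 0.05], [0.05, 0.95]])
    params.pi0 = np.array([0.5, 0.5])
    x, z = arhmm.sample(params, 2000, seed=0)
    dec = arhmm.posterior_decode(params, x)
    np.testing.assert_allclose(dec.posterior.sum(axis=1), 1.0, atol=1e-12)
    assert np.mean(dec.labels == z) > 0.98
    np.testing.assert_array_equal(dec.labels, np.argmax(dec.posterior, axis=1))
    # K=1: constant labels, unit posteriors
    p1 = random_params(1, 0, 2, rng)
    d1 = arhmm.posterior_decode(p1, x)
    assert (d1.labels == 0).all() and (d1.posterior == 1.0).all()


def test_first_lag_frames_inherit_first_decodable_label():
    rng = np.random.default_rng(6)
    params = random_params(2, 2, 2, rng)
    x = rng.normal(0, 1, (30, 2))
    dec = arhmm.posterior_decode(params, x)
    assert dec.labels.shape == (30,)
    assert dec.labels[0] == dec.labels[1] == dec.labels[2]
    np.testing.assert_array_equal(dec.posterior[0], dec.posterior[2])


def viterbi_bruteforce(params, x):
    from itertools import product

    T = x.shape[0]
    n = T - params.L
    best, best_path = -np.inf, None
    for path in product(range(params.K), repeat=n):
        lp = np.log(params.pi0[path[0]])
        for a, b in zip(path[:-1], path[1:]):
            lp += np.log(params.Phi[a, b])
        for i, k in enumerate(path):
            t = params.L + i
            mean = params.mu[k].copy()
            for l in range(1, params.L + 1):
                mean = mean + params.A[k, l - 1] @ x[t - l]
            lp += multivariate_normal.logpdf(x[t], mean, params.Sigma[k])
        if lp > best + 1e-12:
            best, best_path = lp, path
    return np.array(best_path)


def test_viterbi_matches_bruteforce_small_instances():
    rng = np.random.default_rng(7)
    for trial in range(20):
        K = int(rng.integers(2, 4))
        L = int(rng.integers(0, 2))
        d = 2
        T = int(rng.integers(L + 2, 8))
        params = random_params(K, L, d, rng)
        x = rng.normal(0, 1, (T, d))
        got = arhmm.viterbi(params, x)[params.L :]
        want = viterbi_bruteforce(params, x)
        np.testing.assert_array_equal(got, want)


def test_viterbi_follows_deterministic_chain():
    rng = np.random.default_rng(8)
    params = random_params(3, 0, 2, rng)
    params.Phi = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    params.pi0 = np.array([1.0, 0.0, 0.0])
    x = rng.normal(0, 1, (9, 2))
    path = arhmm.viterbi(params, x)
    np.testing.assert_array_equal(path, np.arange(9) % 3)


def test_sample_moments():
    # near-degenerate emission -> sequence pinned at the bias
    p = ARHMMParams(
        K=1, L=0, d=2, A=np.zeros((1, 0, 2, 2)), mu=np.array([[1.5, -2.0]]),
        Sigma=1e-18 * np.eye(2)[None], Phi=np.ones((1, 1)), pi0=np.ones(1),
    )
    x, _ = arhmm.sample(p, 100, seed=0)
    np.testing.assert_allclose(x, np.tile([1.5, -2.0], (100, 1)), atol=1e-6)
    # AR(1) with A = 0.5 I: lag-1 regression coefficient ~ 0.5
    p2 = ARHMMParams(
        K=1, L=1, d=2, A=0.5 * np.eye(2)[None, None], mu=np.zeros((1, 2)),
        Sigma=np.eye(2)[None], Phi=np.ones((1, 1)), pi0=np.ones(1),
    )
    x2, _ = arhmm.sample(p2, 50_000, seed=1)
    num = np.sum(x2[1:] * x2[:-1], axis=0)
    den = np.sum(x2[:-1] ** 2, axis=0)
    np.testing.assert_allclose(num / den, [0.5, 0.5], atol=0.02)


def test_sample_occupancy_matches_stationary_distribution():
    rng = np.random.default_rng(9)
    params = random_params(3, 0, 2, rng)
    z = arhmm.sample_states(params, 100_000, seed=2)
    occ = np.bincount(z, minlength=3) / z.size
    np.testing.assert_allclose(
        occ, arhmm.stationary_distribution(params.Phi), atol=0.01
    )


def test_sample_determinism_and_overflow_guard():
    truth = default_truth(K=2, L=1, d=3, seed=0)
    x1, z1 = arhmm.sample(truth, 500, seed=42)
    x2, z2 = arhmm.sample(truth, 500, seed=42)
    np.testing.assert_array_equal(x1, x2)
    np.testing.assert_array_equal(z1, z2)
    unstable = ARHMMParams(
        K=1, L=1, d=2, A=2.0 * np.eye(2)[None, None], mu=np.zeros((1, 2)),
        Sigma=np.eye(2)[None], Phi=np.ones((1, 1)), pi0=np.ones(1),
    )
    with pytest.raises(FloatingPointError, match="spectral"):
        arhmm.sample(unstable, 200, seed=0)


def test_aic_formula_and_parameter_count():
    rng = np.random.default_rng(10)
    p = random_params(1, 0, 2, rng)
    assert p.n_parameters() == 5  # d mean + d(d+1)/2 cov for K=1, L=0
    x = rng.normal(0, 1, (20, 2))
    fit = arhmm.FitResult(p, np.array([0.0]), True, 0, 1)
    ll = arhmm.log_likelihood(p, [x])
    assert arhmm.aic(fit, [x]) == pytest.approx(2 * 5 - 2 * ll, abs=1e-10)
    # more parameters at equal likelihood -> larger AIC
    p2 = random_params(2, 0, 2, rng)
    assert p2.n_parameters() > p.n_parameters()


def test_invalid_inputs_rejected():
    rng = np.random.default_rng(11)
    with pytest.raises(ValueError):
        arhmm.fit_em([rng.normal(0, 1, (50, 2))], K=0, L=0)
    with pytest.raises(ValueError):
        arhmm.fit_em([rng.normal(0, 1, (50, 2))], K=1, L=-1)
    params = random_params(1, 0, 2, rng)
    bad = np.full((10, 2), np.nan)
    with pytest.raises(ValueError, match="finite"):
        arhmm.log_likelihood(params, [bad])


def test_params_round_trip_through_file(tmp_path):
    rng = np.random.default_rng(12)
    p = random_params(3, 2, 2, rng)
    p.save(tmp_path / "m.json")
    back = ARHMMParams.load(tmp_path / "m.json")
    np.testing.assert_allclose(back.A, p.A, atol=1e-15)
    np.testing.assert_allclose(back.Phi, p.Phi, atol=1e-15)
    assert back.K == p.K and back.L == p.L and back.d == p.d
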