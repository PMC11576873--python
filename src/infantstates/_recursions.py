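"""Log-space forward/backward and Viterbi recursions (numba-compiled).

These inner loops dominate EM runtime; everything else in the model is
vectorised numpy.  All recursions work on a (T, K) matrix of per-frame
emission log-densities, a (K, K) log transition matrix and a length-K log
initial distribution.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _logsumexp1(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - m)
    return m + np.log(s)


@njit(cache=True)
def forward_loglik(log_pi0, log_phi, log_b):
    """Marginal log-likelihood via the forward recursion."""
    T, K = log_b.shape
    prev = np.empty(K)
    cur = np.empty(K)
    tmp = np.empty(K)
    for k in range(K):
        prev[k] = log_pi0[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            for j in range(K):
                tmp[j] = prev[j] + log_phi[j, k]
            cur[k] = _logsumexp1(tmp) + log_b[t, k]
        prev, cur = cur, prev
    return _logsumexp1(prev)


@njit(cache=True)
def forward_backward(log_pi0, log_phi, log_b):
    """Posterior state marginals and expected transition counts.

    Returns (loglik, gamma (T, K), xi_sum (K, K), gamma0 (K,)) where
    xi_sum accumulates expected transitions over all time steps and
    gamma0 is the posterior over the first frame.
    """
    T, K = log_b.shape
    la = np.empty((T, K))
    lb = np.empty((T, K))
    tmp = np.empty(K)
    for k in range(K):
        la[0, k] = log_pi0[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            for j in range(K):
                tmp[j] = la[t - 1, j] + log_phi[j, k]
            la[t, k] = _logsumexp1(tmp) + log_b[t, k]
    ll = _logsumexp1(la[T - 1])
    for k in range(K):
        lb[T - 1, k] = 0.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            for k in range(K):
                tmp[k] = log_phi[j, k] + log_b[t + 1, k] + lb[t + 1, k]
            lb[t, j] = _logsumexp1(tmp)
    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = np.exp(la[t, k] + lb[t, k] - ll)
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    xi = np.zeros((K, K))
    for t in range(T - 1):
        s = 0.0
        for j in range(K):
            for k in range(K):
                tmp_v = np.exp(
                    la[t, j] + log_phi[j, k] + log_b[t + 1, k] + lb[t + 1, k] - ll
                )
                xi[j, k] += tmp_v
                s += tmp_v
    gamma0 = gamma[0].copy()
    return ll, gamma, xi, gamma0


@njit(cache=True)
def viterbi_path(log_pi0, log_phi, log_b):
    """Most probable joint path; ties broken toward the lower state index."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi0[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_phi[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_phi[j, k]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = j
            delta[t, k] = best + log_b[t, k]
            back[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
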