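"""Numba kernels for the per-trace Gaussian-emission HMM.

Scaled forward-backward, EM updates and Viterbi decoding, all supporting
missing observations: frames flagged invalid contribute a unit emission
likelihood, so the chain bridges them through the transition structure
without imputing values.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT2PI = np.sqrt(2.0 * np.pi)
_SD_FLOOR = 1e-3


@njit(cache=False)
def _emissions(obs, valid, means, sds):
    T = obs.shape[0]
    K = means.shape[0]
    b = np.ones((T, K))
    for t in range(T):
        if not valid[t]:
            continue
        for k in range(K):
            z = (obs[t] - means[k]) / sds[k]
            b[t, k] = np.exp(-0.5 * z * z) / (sds[k] * _SQRT2PI)
            if b[t, k] < 1e-300:
                b[t, k] = 1e-300
    return b


@njit(cache=False)
def _forward_backward(obs, valid, means, sds, A, pi):
    """Returns (loglik, gamma[T,K], xi_sum[K,K])."""
    T = obs.shape[0]
    K = means.shape[0]
    b = _emissions(obs, valid, means, sds)
    alpha = np.zeros((T, K))
    c = np.zeros(T)
    for k in range(K):
        alpha[0, k] = pi[k] * b[0, k]
    c[0] = alpha[0].sum()
    if c[0] <= 0.0:
        c[0] = 1e-300
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = s * b[t, j]
        c[t] = alpha[t].sum()
        if c[t] <= 0.0:
            c[t] = 1e-300
        alpha[t] /= c[t]
    beta = np.zeros((T, K))
    beta[T - 1] = 1.0
    gamma = np.zeros((T, K))
    gamma[T - 1] = alpha[T - 1]
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += A[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = s / c[t + 1]
        for i in range(K):
            gamma[t, i] = alpha[t, i] * beta[t, i]
        for i in range(K):
            for j in range(K):
                xi[i, j] += alpha[t, i] * A[i, j] * b[t + 1, j] * beta[t + 1, j] / c[t + 1]
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, gamma, xi


@njit(cache=False)
def _em_fit(obs, valid, means0, sds0, A0, pi0, max_iter, tol):
    """EM until the log-likelihood gain drops below ``tol``.

    Returns (means, sds, A, pi, loglik, n_iter)."""
    means = means0.copy()
    sds = sds0.copy()
    A = A0.copy()
    pi = pi0.copy()
    K = means.shape[0]
    prev = -np.inf
    loglik = -np.inf
    for it in range(max_iter):
        loglik, gamma, xi = _forward_backward(obs, valid, means, sds, A, pi)
        # M-step
        for k in range(K):
            pi[k] = gamma[0, k]
        psum = pi.sum()
        if psum > 0:
            pi /= psum
        for i in range(K):
            rs = xi[i].sum()
            if rs > 0:
                for j in range(K):
                    A[i, j] = xi[i, j] / rs
        for k in range(K):
            wsum = 0.0
            xsum = 0.0
            for t in range(obs.shape[0]):
                if valid[t]:
                    wsum += gamma[t, k]
                    xsum += gamma[t, k] * obs[t]
            if wsum > 1e-12:
                m = xsum / wsum
                v = 0.0
                for t in range(obs.shape[0]):
                    if valid[t]:
                        d = obs[t] - m
                        v += gamma[t, k] * d * d
                means[k] = m
                sds[k] = max(np.sqrt(v / wsum), _SD_FLOOR)
        if loglik - prev < tol and it > 0:
            break
        prev = loglik
    loglik, _, _ = _forward_backward(obs, valid, means, sds, A, pi)
    return means, sds, A, pi, loglik, it + 1


@njit(cache=False)
def _viterbi(obs, valid, means, sds, A, pi):
    """Most probable state path (log-space)."""
    T = obs.shape[0]
    K = means.shape[0]
    b = _emissions(obs, valid, means, sds)
    logb = np.log(b)
    logA = np.log(A + 1e-300)
    delta = np.zeros((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = np.log(pi[k] + 1e-300) + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, delta[T - 1].max()


def path_log_likelihood(obs, valid, means, sds, A, pi, path) -> float:
    """Joint log-probability of a given state path and the observations
    (reference implementation used for Viterbi-optimality checks)."""
    obs = np.asarray(obs, float)
    ll = np.log(pi[path[0]] + 1e-300)
    for t in range(len(path)):
        if t > 0:
            ll += np.log(A[path[t - 1], path[t]] + 1e-300)
        if valid[t]:
            z = (obs[t] - means[path[t]]) / sds[path[t]]
            ll += -0.5 * z * z - np.log(sds[path[t]] * _SQRT2PI)
    return float(ll)
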