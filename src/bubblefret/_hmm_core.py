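"""Scaled forward-backward and Viterbi kernels.

Written loop-wise so numba can jit them; falls back to the interpreted
versions when numba is unavailable.  ``pi`` and ``A`` need not be normalized
(variational E-steps pass exponentiated expected logs, whose rows sum to
less than one); the scaling constants absorb the deficit into ``logZ``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(func):
            return func

        return deco


@njit(cache=True)
def forward_backward(logB, pi, A):
    """Posterior marginals, summed two-slice marginals and log normalizer.

    logB: (T, K) log emission weights; pi: (K,) initial weights; A: (K, K)
    transition weights.  Returns (gamma, xi_sum, logZ).
    """
    T, K = logB.shape
    B = np.empty((T, K))
    mx = np.empty(T)
    for t in range(T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        mx[t] = m
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    gamma = np.empty((T, K))
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                term = A[j, k] * B[t + 1, k] * beta[t + 1, k]
                xi_sum[j, k] += alpha[t, j] * term / c[t + 1]
                acc += term
            beta[t, j] = acc / c[t + 1]
        g = 0.0
        for j in range(K):
            gamma[t, j] = alpha[t, j] * beta[t, j]
            g += gamma[t, j]
        for j in range(K):
            gamma[t, j] /= g

    logZ = 0.0
    for t in range(T):
        logZ += np.log(c[t]) + mx[t]
    return gamma, xi_sum, logZ


@njit(cache=True)
def viterbi(logB, log_pi, log_A):
    """Most probable state path by dynamic programming (ties -> lowest index)."""
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_A[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_A[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
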