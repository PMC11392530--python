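"""Scaled forward-backward kernels (numba-compiled inner loops)."""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward_core", "forward_core", "forward_backward_varying"]


@njit(cache=True)
def forward_core(pi, A, B):
    """Scaled forward pass.  B is the (n_steps, K) emission-likelihood matrix
    (any positive scaling per row; add the row log-shifts externally).
    Returns the log-likelihood."""
    n, K = B.shape
    alpha = pi * B[0]
    c = alpha.sum()
    loglik = np.log(c)
    alpha = alpha / c
    for t in range(1, n):
        nxt = np.zeros(K)
        for i in range(K):
            ai = alpha[i]
            if ai > 0.0:
                for j in range(K):
                    nxt[j] += ai * A[i, j]
        nxt *= B[t]
        c = nxt.sum()
        loglik += np.log(c)
        alpha = nxt / c
    return loglik


@njit(cache=True)
def forward_backward_core(pi, A, B):
    """Scaled forward-backward with sufficient statistics.

    Returns (loglik, gamma, xi_sum, gamma0) where gamma[t] is the posterior
    over hidden states at step t (rows sum to 1), xi_sum the expected
    transition-count matrix summed over steps and gamma0 = gamma[0].
    """
    n, K = B.shape
    alpha = np.empty((n, K))
    cs = np.empty(n)
    a = pi * B[0]
    cs[0] = a.sum()
    alpha[0] = a / cs[0]
    for t in range(1, n):
        nxt = np.zeros(K)
        for i in range(K):
            ai = alpha[t - 1, i]
            if ai > 0.0:
                for j in range(K):
                    nxt[j] += ai * A[i, j]
        nxt *= B[t]
        cs[t] = nxt.sum()
        alpha[t] = nxt / cs[t]

    beta = np.ones(K)
    gamma = np.empty((n, K))
    xi = np.zeros((K, K))
    gamma[n - 1] = alpha[n - 1] * beta
    gamma[n - 1] /= gamma[n - 1].sum()
    for t in range(n - 2, -1, -1):
        bb = B[t + 1] * beta
        # xi[i, j] += alpha[t, i] A[i, j] B[t+1, j] beta[j] / c[t+1]
        for i in range(K):
            ai = alpha[t, i]
            if ai > 0.0:
                for j in range(K):
                    xi[i, j] += ai * A[i, j] * bb[j] / cs[t + 1]
        nb = np.zeros(K)
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += A[i, j] * bb[j]
            nb[i] = s / cs[t + 1]
        beta = nb
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    loglik = np.log(cs).sum()
    return loglik, gamma, xi, gamma[0]


@njit(cache=True)
def forward_backward_varying(pi, As, B):
    """Forward-backward posterior decoding with a per-step transition matrix.

    ``As[t]`` carries the state from step t to t+1 (shape (n-1, K, K)).
    Returns (loglik, gamma).
    """
    n, K = B.shape
    alpha = np.empty((n, K))
    cs = np.empty(n)
    a = pi * B[0]
    cs[0] = a.sum()
    alpha[0] = a / cs[0]
    for t in range(1, n):
        nxt = np.zeros(K)
        for i in range(K):
            ai = alpha[t - 1, i]
            if ai > 0.0:
                for j in range(K):
                    nxt[j] += ai * As[t - 1, i, j]
        nxt *= B[t]
        cs[t] = nxt.sum()
        alpha[t] = nxt / cs[t]
    beta = np.ones(K)
    gamma = np.empty((n, K))
    gamma[n - 1] = alpha[n - 1]
    for t in range(n - 2, -1, -1):
        bb = B[t + 1] * beta
        nb = np.zeros(K)
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += As[t, i, j] * bb[j]
            nb[i] = s / cs[t + 1]
        beta = nb
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    return np.log(cs).sum(), gamma
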