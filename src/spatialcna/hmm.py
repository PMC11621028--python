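"""Log-space hidden Markov model primitives.

Both genome-axis models in this package (the pseudobulk phasing model and
the copy-number-state model) are HMMs with custom emission matrices and
chains that reset at chromosome boundaries.  The routines here operate on a
single chain given a precomputed ``log_emission`` matrix of shape
``(n_obs, n_states)``; callers loop over chains and sum.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "forward",
    "backward",
    "forward_backward",
    "viterbi",
    "enumerate_loglik",
]


def forward(log_emission: np.ndarray, log_trans: np.ndarray, log_start: np.ndarray):
    """Forward recursion; returns (log_alpha, log_likelihood)."""
    T, K = log_emission.shape
    log_alpha = np.empty((T, K))
    log_alpha[0] = log_start + log_emission[0]
    for t in range(1, T):
        log_alpha[t] = (
            logsumexp(log_alpha[t - 1][:, None] + log_trans, axis=0) + log_emission[t]
        )
    return log_alpha, logsumexp(log_alpha[-1])


def backward(log_emission: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    T, K = log_emission.shape
    log_beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(
            log_trans + (log_emission[t + 1] + log_beta[t + 1])[None, :], axis=1
        )
    return log_beta


def forward_backward(log_emission, log_trans, log_start):
    """E-step for one chain.

    Returns
    -------
    loglik : float
    gamma : (T, K) posterior state probabilities
    xi_sum : (K, K) expected transition counts summed over time
    """
    log_alpha, loglik = forward(log_emission, log_trans, log_start)
    log_beta = backward(log_emission, log_trans)
    log_gamma = log_alpha + log_beta - loglik
    gamma = np.exp(log_gamma)
    T, K = log_emission.shape
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        log_xi = (
            log_alpha[t][:, None]
            + log_trans
            + log_emission[t + 1][None, :]
            + log_beta[t + 1][None, :]
            - loglik
        )
        xi_sum += np.exp(log_xi)
    return loglik, gamma, xi_sum


def viterbi(log_emission, log_trans, log_start) -> np.ndarray:
    """MAP state path. Ties break toward the lower state index (argmax rule)."""
    T, K = log_emission.shape
    score = np.empty((T, K))
    back = np.zeros((T, K), dtype=int)
    score[0] = log_start + log_emission[0]
    for t in range(1, T):
        cand = score[t - 1][:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        score[t] = cand[back[t], np.arange(K)] + log_emission[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(score[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def enumerate_loglik(log_emission, log_trans, log_start) -> float:
    """Exhaustive sum over all state paths (oracle; exponential in T)."""
    T, K = log_emission.shape
    total = -np.inf
    paths = np.stack(np.meshgrid(*([np.arange(K)] * T), indexing="ij"), axis=-1)
    paths = paths.reshape(-1, T)
    for p in paths:
        lp = log_start[p[0]] + log_emission[0, p[0]]
        for t in range(1, T):
            lp += log_trans[p[t - 1], p[t]] + log_emission[t, p[t]]
        total = np.logaddexp(total, lp)
    return float(total)
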