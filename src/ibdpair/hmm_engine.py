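"""Exact HMM inference for one pair: forward/backward, posteriors, Viterbi.

The hidden chain is the 3-state IBD process; emissions are the per-site
probabilities from :func:`ibdpair.ibd_model.emission_matrix`.  All passes
use per-site scaling so chains of millions of sites cannot underflow, and
the total log-likelihood is recovered as the sum of log scale factors.
Chromosomes are independent: at the first site of each chromosome the chain
restarts from the stationary distribution (k0, k1, k2).

The inner loops are compiled with numba; typical genome-scale inputs decode
in milliseconds, which is what makes numerical maximum-likelihood fitting
of (R, alpha) practical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .ibd_model import (
    RelatednessParams,
    SiteTable,
    build_rate_matrix,
    transition_stack,
)

__all__ = [
    "DecodeResult",
    "log_likelihood",
    "posterior_decode",
    "viterbi",
    "decode",
    "path_log_probability",
]

_NEG_INF = -1e300


@dataclass
class DecodeResult:
    """Decoding output for one pair.

    Attributes
    ----------
    loglik :
        Total log-likelihood (nats) of the data under (R, alpha).
    posteriors :
        L x 3 matrix of P(X_l = x | all data); rows sum to 1.  ``None``
        until posterior decoding has run.
    viterbi_path :
        Length-L most-probable state path in {0, 1, 2}; ``None`` until
        Viterbi has run.
    scale_log :
        Per-site log scaling factors; their sum equals ``loglik``.
    """

    loglik: float
    posteriors: np.ndarray | None = None
    viterbi_path: np.ndarray | None = None
    scale_log: np.ndarray | None = None


@njit(cache=True)
def _forward(e, trans, new_chrom, pi):
    L = e.shape[0]
    fwd = np.empty((L, 3))
    scale_log = np.empty(L)
    for l in range(L):
        if new_chrom[l]:
            for x in range(3):
                fwd[l, x] = pi[x] * e[l, x]
        else:
            for x in range(3):
                s = 0.0
                for y in range(3):
                    s += fwd[l - 1, y] * trans[l, y, x]
                fwd[l, x] = s * e[l, x]
        c = fwd[l, 0] + fwd[l, 1] + fwd[l, 2]
        if not (c > 0.0) or not np.isfinite(c):
            # signal underflow/invalid emission by site index via scale_log
            scale_log[l] = np.nan
            return fwd, scale_log
        scale_log[l] = np.log(c)
        for x in range(3):
            fwd[l, x] /= c
    return fwd, scale_log


@njit(cache=True)
def _backward(e, trans, new_chrom, scale_log):
    L = e.shape[0]
    bwd = np.empty((L, 3))
    for x in range(3):
        bwd[L - 1, x] = 1.0
    for l in range(L - 2, -1, -1):
        if new_chrom[l + 1]:
            for x in range(3):
                bwd[l, x] = 1.0
        else:
            c = np.exp(scale_log[l + 1])
            for x in range(3):
                s = 0.0
                for y in range(3):
                    s += trans[l + 1, x, y] * e[l + 1, y] * bwd[l + 1, y]
                bwd[l, x] = s / c
    return bwd


@njit(cache=True)
def _viterbi(e, trans, new_chrom, pi):
    L = e.shape[0]
    loge = np.empty((L, 3))
    for l in range(L):
        for x in range(3):
            v = e[l, x]
            loge[l, x] = np.log(v) if v > 0.0 else _NEG_INF
    logpi = np.empty(3)
    for x in range(3):
        logpi[x] = np.log(pi[x]) if pi[x] > 0.0 else _NEG_INF
    delta = np.empty((L, 3))
    psi = np.zeros((L, 3), dtype=np.int8)
    for l in range(L):
        if new_chrom[l]:
            for x in range(3):
                delta[l, x] = logpi[x] + loge[l, x]
        else:
            for x in range(3):
                best = _NEG_INF * 2.0
                arg = 0
                for y in range(3):
                    t = trans[l, y, x]
                    logt = np.log(t) if t > 0.0 else _NEG_INF
                    v = delta[l - 1, y] + logt
                    if v > best:  # strict: ties keep the lower state index
                        best = v
                        arg = y
                delta[l, x] = best + loge[l, x]
                psi[l, x] = arg
    path = np.empty(L, dtype=np.int8)
    logp = 0.0
    end = L - 1
    for l in range(L - 1, -1, -1):
        if l == end:
            best = _NEG_INF * 2.0
            arg = 0
            for x in range(3):
                if delta[l, x] > best:
                    best = delta[l, x]
                    arg = x
            path[l] = arg
            logp += best
        if new_chrom[l]:
            end = l - 1  # previous chromosome ends at l - 1
        elif l > 0:
            path[l - 1] = psi[l, path[l]]
    return path, logp


def _prepare(e: np.ndarray, sites: SiteTable, params: RelatednessParams):
    e = np.ascontiguousarray(e, dtype=float)
    if e.ndim != 2 or e.shape[1] != 3:
        raise ValueError("emission matrix must be L x 3")
    if e.shape[0] == 0:
        raise ValueError("no sites to decode")
    if e.shape[0] != len(sites):
        raise ValueError(
            f"emissions have {e.shape[0]} rows but site table has {len(sites)}"
        )
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite emission probabilities")
    p = params.floored()
    q = build_rate_matrix(p)
    trans = transition_stack(q, sites.dist_prev, sites.new_chrom)
    return e, trans, sites.new_chrom, p.k


def log_likelihood(
    e: np.ndarray, sites: SiteTable, params: RelatednessParams
) -> float:
    """Total log-likelihood of the pair's data given (R, alpha)."""
    e, trans, new_chrom, pi = _prepare(e, sites, params)
    _, scale_log = _forward(e, trans, new_chrom, pi)
    return _checked_loglik(scale_log)


def _checked_loglik(scale_log: np.ndarray) -> float:
    bad = np.nonzero(np.isnan(scale_log))[0]
    if bad.size:
        raise FloatingPointError(
            f"forward pass underflowed / hit zero likelihood at site {bad[0]}"
        )
    return float(scale_log.sum())


def posterior_decode(
    e: np.ndarray, sites: SiteTable, params: RelatednessParams
) -> DecodeResult:
    """Per-site marginal state probabilities via scaled forward-backward."""
    e, trans, new_chrom, pi = _prepare(e, sites, params)
    fwd, scale_log = _forward(e, trans, new_chrom, pi)
    loglik = _checked_loglik(scale_log)
    bwd = _backward(e, trans, new_chrom, scale_log)
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return DecodeResult(loglik=loglik, posteriors=post, scale_log=scale_log)


def viterbi(
    e: np.ndarray, sites: SiteTable, params: RelatednessParams
) -> DecodeResult:
    """Most probable IBD state path, computed in log space.

    Ties are broken toward the lower state index, both in the recursion and
    in the backtracking, so the output is deterministic.
    """
    e, trans, new_chrom, pi = _prepare(e, sites, params)
    _, scale_log = _forward(e, trans, new_chrom, pi)
    loglik = _checked_loglik(scale_log)
    path, _ = _viterbi(e, trans, new_chrom, pi)
    return DecodeResult(
        loglik=loglik, viterbi_path=path.astype(np.int8), scale_log=scale_log
    )


def path_log_probability(
    e: np.ndarray, sites: SiteTable, params: RelatednessParams, path: np.ndarray
) -> float:
    """Joint log-probability of a given state path and the data.

    Useful as an independent score: the Viterbi path maximises this over
    all 3^L paths.
    """
    e, trans, new_chrom, pi = _prepare(e, sites, params)
    path = np.asarray(path)
    with np.errstate(divide="ignore"):
        logp = 0.0
        for l in range(len(path)):
            p = pi[path[l]] if new_chrom[l] else trans[l, path[l - 1], path[l]]
            logp += np.log(p) + np.log(e[l, path[l]])
    return float(logp)


def decode(
    e: np.ndarray, sites: SiteTable, params: RelatednessParams
) -> DecodeResult:
    """Posterior decoding and Viterbi in one pass; returns a full result."""
    res = posterior_decode(e, sites, params)
    vit = viterbi(e, sites, params)
    res.viterbi_path = vit.viterbi_path
    return res
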