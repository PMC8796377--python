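"""Independent brute-force oracles used by the tests.

Everything here is deliberately written without reusing the package's HMM or
transition code paths: transition matrices come straight from
``scipy.linalg.expm`` on an inline rate matrix, likelihoods and posteriors
from explicit enumeration of all 3^L state paths.  Slow by design — only for
tiny problems.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def rate_matrix(k0: float, k1: float, k2: float, alpha: float) -> np.ndarray:
    return np.array(
        [
            [-alpha * k1, alpha * k1, 0.0],
            [alpha * k0, -alpha * (k0 + k2), alpha * k2],
            [0.0, alpha * k1, -alpha * k1],
        ]
    )


def taylor_expm(q: np.ndarray, d: float, terms: int = 40) -> np.ndarray:
    """Truncated Taylor series sum_{n<terms} (Q d)^n / n!."""
    out = np.eye(3)
    term = np.eye(3)
    for n in range(1, terms):
        term = term @ (q * d) / n
        out = out + term
    return out


def enumerate_paths(e, dist_prev, new_chrom, k, alpha):
    """Exact likelihood, posteriors and best path by summing all 3^L paths.

    Returns (loglik, posteriors (L,3), best_path, best_path_logprob) where
    the best path maximises the joint probability; among ties the
    lexicographically smallest (lowest state indices first) wins, matching
    the tie rule the Viterbi implementation documents.
    """
    e = np.asarray(e, dtype=float)
    L = e.shape[0]
    q = rate_matrix(*k, alpha)
    pi = np.asarray(k, dtype=float)
    trans = [None] * L
    for l in range(L):
        if not new_chrom[l]:
            trans[l] = expm(q * dist_prev[l])
    total = 0.0
    post = np.zeros((L, 3))
    best_p = -1.0
    best_path = None
    for path in itertools.product((0, 1, 2), repeat=L):
        p = 1.0
        for l in range(L):
            p *= pi[path[l]] if new_chrom[l] else trans[l][path[l - 1], path[l]]
            p *= e[l, path[l]]
        total += p
        for l in range(L):
            post[l, path[l]] += p
        if p > best_p:  # strict: first (lexicographically smallest) tie wins
            best_p = p
            best_path = path
    return np.log(total), post / total, np.array(best_path), np.log(best_p)


def freq_grid_search(gls: np.ndarray, step: float = 1e-4) -> float:
    """Site allele frequency maximising the marginal likelihood on a grid.

    ``gls`` is (N, 3) for one site; the marginal likelihood is
    prod_n sum_g HWE(f)[g] * gls[n, g].
    """
    grid = np.arange(step, 1.0, step)
    hwe = np.stack([(1 - grid) ** 2, 2 * grid * (1 - grid), grid ** 2], axis=1)
    ll = np.log(np.einsum("fg,ng->nf", hwe, gls)).sum(axis=0)
    return float(grid[np.argmax(ll)])
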