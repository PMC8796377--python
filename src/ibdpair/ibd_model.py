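"""Probabilistic core for pairwise local IBD inference.

At every diallelic site a non-inbred pair of diploids shares 0, 1 or 2
alleles identical by descent (IBD).  Along the genome the IBD state is
modelled as a continuous-time Markov chain (CTMC) whose stationary
distribution is the vector of relatedness coefficients ``R = (k0, k1, k2)``
and whose overall switch rate per unit genetic distance is ``alpha``.
Observed data enter only through genotype likelihoods, so the model works
directly on low-depth sequencing data without calling genotypes.

This module provides the rate matrix, its matrix exponential (the HMM
transition kernel), Hardy-Weinberg genotype priors, the conditional
distribution of one individual's genotype given the other's under each IBD
state, and the per-site emission probabilities obtained by summing the nine
genotype pairs against the two genotype-likelihood triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PARAM_FLOOR",
    "RelatednessParams",
    "RateMatrix",
    "SiteTable",
    "PairGL",
    "build_rate_matrix",
    "transition_matrix",
    "transition_stack",
    "genotype_prior",
    "conditional_genotype_prob",
    "emission_matrix",
]

#: Floor applied to k components (and to alpha) so that degenerate
#: relationships such as parent-offspring (k0 = k2 = 0) keep the chain
#: irreducible and the likelihood finite.
PARAM_FLOOR = 1e-8


@dataclass(frozen=True)
class RelatednessParams:
    """Relatedness coefficients and IBD switch rate.

    Parameters
    ----------
    k0, k1, k2 :
        Genome-wide proportions of loci at which the pair shares 0, 1 or 2
        alleles IBD.  Must lie in [0, 1] and sum to 1.
    alpha :
        Rate of change of the IBD state per Morgan of genetic distance.
        Must be positive.
    """

    k0: float
    k1: float
    k2: float
    alpha: float

    def __post_init__(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(not np.isfinite(k) or k < 0.0 or k > 1.0 for k in ks):
            raise ValueError(f"k coefficients must lie in [0, 1], got {ks}")
        if abs(sum(ks) - 1.0) > 1e-12:
            raise ValueError(f"k0 + k1 + k2 must equal 1, got {sum(ks)!r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0.0:
            raise ValueError(f"alpha must be positive, got {self.alpha!r}")

    @property
    def k(self) -> np.ndarray:
        """The stationary distribution (k0, k1, k2) as an array."""
        return np.array([self.k0, self.k1, self.k2])

    def floored(self, floor: float = PARAM_FLOOR) -> "RelatednessParams":
        """Clamp k components to ``floor`` and renormalise.

        Keeps boundary relationships (e.g. parent-offspring with
        k0 = k2 = 0) inside the simplex interior so the rate matrix stays
        irreducible.
        """
        k = np.maximum(self.k, floor)
        k = k / k.sum()
        return RelatednessParams(k[0], k[1], k[2], max(self.alpha, floor))

    @classmethod
    def from_k(cls, k, alpha: float) -> "RelatednessParams":
        k = np.asarray(k, dtype=float)
        return cls(k[0], k[1], k[2], alpha)


@dataclass(frozen=True)
class RateMatrix:
    """Instantaneous rate matrix Q of the IBD CTMC (per Morgan)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (3, 3):
            raise ValueError("rate matrix must be 3x3")
        object.__setattr__(self, "q", q)


def build_rate_matrix(params: RelatednessParams) -> RateMatrix:
    """Build the 3-state IBD rate matrix.

    ::

        Q = [ -a*k1        a*k1         0     ]
            [  a*k0       -a*(k0+k2)    a*k2  ]
            [  0           a*k1        -a*k1  ]

    Direct jumps between 0 and 2 alleles IBD are impossible; the chain has
    ``(k0, k1, k2)`` as stationary distribution.
    """
    p = params  # validation happened in the dataclass
    a = p.alpha
    q = np.array(
        [
            [-a * p.k1, a * p.k1, 0.0],
            [a * p.k0, -a * (p.k0 + p.k2), a * p.k2],
            [0.0, a * p.k1, -a * p.k1],
        ]
    )
    return RateMatrix(q)


def _expm_eig(q: np.ndarray, dists: np.ndarray) -> np.ndarray:
    """exp(q*d) for a batch of distances via eigendecomposition.

    The IBD rate matrix has real eigenvalues {0, -alpha*k1, -alpha}; a plain
    eigendecomposition is exact away from the degenerate case k1 ~ 1.
    Raises ``numpy.linalg.LinAlgError`` if the eigenvector matrix is
    (numerically) singular so the caller can fall back.
    """
    w, v = np.linalg.eig(q)
    vinv = np.linalg.inv(v)
    if np.linalg.cond(v) > 1e10:
        raise np.linalg.LinAlgError("near-defective eigenvector matrix")
    ew = np.exp(np.outer(dists, w))  # (D, 3)
    t = np.einsum("ab,db,bc->dac", v, ew, vinv)
    return np.ascontiguousarray(t.real)


def _expm_batch(q: np.ndarray, dists: np.ndarray) -> np.ndarray:
    """Transition matrices for a batch of distances, with validation.

    Eigendecomposition first; scaling-and-squaring (``scipy.linalg.expm``)
    as fallback for near-degenerate spectra.  Entries are clamped to [0, 1]
    and rows renormalised provided |row sum - 1| < 1e-9.
    """
    try:
        t = _expm_eig(q, dists)
    except np.linalg.LinAlgError:
        t = np.stack([expm(q * d) for d in dists])
    rowsums = t.sum(axis=2)
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        # eigen route lost accuracy (huge alpha*d etc.) -- retry with expm
        t = np.stack([expm(q * d) for d in dists])
        rowsums = t.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise FloatingPointError(
                "transition matrix rows do not sum to 1 within 1e-9"
            )
    t = np.clip(t, 0.0, 1.0)
    t /= t.sum(axis=2, keepdims=True)
    return t


def transition_matrix(q: RateMatrix, d: float) -> np.ndarray:
    """Transition probabilities T(d) = exp(Q*d) over genetic distance ``d``.

    Parameters
    ----------
    q :
        Rate matrix from :func:`build_rate_matrix`.
    d :
        Genetic distance in Morgans; must be >= 0.
    """
    if d < 0:
        raise ValueError(f"genetic distance must be >= 0, got {d!r}")
    return _expm_batch(q.q, np.array([float(d)]))[0]


def transition_stack(
    q: RateMatrix, dist_prev: np.ndarray, new_chrom: np.ndarray
) -> np.ndarray:
    """Per-site transition matrices for an ordered site table.

    Distances are deduplicated before exponentiation (thinned data repeat
    the same gap many times).  Rows flagged ``new_chrom`` get an identity
    placeholder; the HMM engine restarts those sites from the stationary
    distribution instead of applying a transition.
    """
    dist_prev = np.asarray(dist_prev, dtype=float)
    if np.any(dist_prev < 0):
        raise ValueError("genetic distances must be >= 0")
    uniq, inv = np.unique(dist_prev, return_inverse=True)
    stack = _expm_batch(q.q, uniq)
    trans = stack[inv]
    trans[new_chrom] = np.eye(3)
    return trans


@dataclass
class SiteTable:
    """Ordered per-site records the HMM runs along.

    Attributes
    ----------
    chrom :
        Chromosome label per site (sites grouped and position-sorted).
    pos :
        1-based physical position in bp, strictly increasing per chromosome.
    alleleA, allelea :
        Allele codes 0..3 for A, C, G, T.  ``alleleA`` is the allele whose
        frequency ``freqA`` refers to and whose copy number the genotype
        coding counts.
    freqA :
        Population frequency of allele A, in (0, 1).
    dist_prev :
        Genetic distance in Morgans to the previous retained site on the
        same chromosome; 0 at the first site of each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    alleleA: np.ndarray
    allelea: np.ndarray
    freqA: np.ndarray
    dist_prev: np.ndarray
    new_chrom: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleleA = np.asarray(self.alleleA, dtype=np.int8)
        self.allelea = np.asarray(self.allelea, dtype=np.int8)
        self.freqA = np.asarray(self.freqA, dtype=float)
        self.dist_prev = np.asarray(self.dist_prev, dtype=float)
        if self.new_chrom is None:
            first = np.ones(len(self.pos), dtype=bool)
            if len(self.pos) > 1:
                first[1:] = self.chrom[1:] != self.chrom[:-1]
            self.new_chrom = first
        else:
            self.new_chrom = np.asarray(self.new_chrom, dtype=bool)
        n = len(self.pos)
        for name in ("chrom", "alleleA", "allelea", "freqA", "dist_prev", "new_chrom"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SiteTable field {name} has mismatched length")
        same = ~self.new_chrom
        if np.any(np.diff(self.pos)[same[1:]] <= 0):
            raise ValueError("positions must be strictly increasing per chromosome")
        if np.any(self.dist_prev < 0):
            raise ValueError("dist_prev must be >= 0")

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "SiteTable":
        """Row subset; genetic distances are not recomputed (caller decides)."""
        return SiteTable(
            self.chrom[idx],
            self.pos[idx],
            self.alleleA[idx],
            self.allelea[idx],
            self.freqA[idx],
            self.dist_prev[idx],
        )

    @classmethod
    def from_positions(
        cls,
        chrom,
        pos,
        freqA,
        alleleA=None,
        allelea=None,
        cm_per_mb: float = 1.0,
        genetic_map=None,
    ) -> "SiteTable":
        """Build a table, deriving ``dist_prev`` from physical positions.

        With ``genetic_map`` (see :func:`ibdpair.io_formats.read_genetic_map`)
        cumulative map positions are linearly interpolated; otherwise a
        constant ``cm_per_mb`` rate is applied.
        """
        from .io_formats import genetic_distances  # deferred: avoid cycle

        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        n = len(pos)
        if alleleA is None:
            alleleA = np.zeros(n, dtype=np.int8)
        if allelea is None:
            allelea = np.ones(n, dtype=np.int8)
        dist_prev, new_chrom = genetic_distances(
            chrom, pos, cm_per_mb=cm_per_mb, genetic_map=genetic_map
        )
        return cls(chrom, pos, alleleA, allelea, np.asarray(freqA, float), dist_prev, new_chrom)


@dataclass
class PairGL:
    """Genotype-likelihood triples for the two individuals of a pair.

    ``gl_i[l, g]`` is P(data at site l for individual i | genotype with g
    copies of allele A); likewise ``gl_j``.  Rows may be arbitrarily scaled
    by positive constants — the model only uses likelihood ratios.
    """

    gl_i: np.ndarray
    gl_j: np.ndarray

    def __post_init__(self) -> None:
        self.gl_i = np.ascontiguousarray(self.gl_i, dtype=float)
        self.gl_j = np.ascontiguousarray(self.gl_j, dtype=float)
        for name, g in (("gl_i", self.gl_i), ("gl_j", self.gl_j)):
            if g.ndim != 2 or g.shape[1] != 3:
                raise ValueError(f"{name} must be an L x 3 array")
            if np.any(g < 0) or not np.all(np.isfinite(g)):
                raise ValueError(f"{name} must be finite and >= 0")
            if np.any(g.sum(axis=1) <= 0):
                raise ValueError(f"{name} has a site with all-zero likelihoods")
        if self.gl_i.shape != self.gl_j.shape:
            raise ValueError("gl_i and gl_j must have identical shape")

    def __len__(self) -> int:
        return self.gl_i.shape[0]

    def swapped(self) -> "PairGL":
        return PairGL(self.gl_j.copy(), self.gl_i.copy())

    def subset(self, idx) -> "PairGL":
        return PairGL(self.gl_i[idx], self.gl_j[idx])


def genotype_prior(f) -> np.ndarray:
    """Hardy-Weinberg genotype prior ((1-f)^2, 2f(1-f), f^2).

    ``f`` is the frequency of allele A; scalar or array (vectorised over
    sites, returning shape (..., 3)).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)


def conditional_genotype_prob(gi: int, f: float, x: int) -> np.ndarray:
    """Distribution of the second genotype given the first and the IBD state.

    With 0 alleles IBD the genotypes are independent (Hardy-Weinberg); with
    2 they are identical; with 1 the shared allele is a uniformly chosen
    allele of ``gi`` and the remaining allele is a fresh draw with
    frequency ``f``.
    """
    if gi not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {gi!r}")
    if x not in (0, 1, 2):
        raise ValueError(f"IBD state must be 0, 1 or 2, got {x!r}")
    return _conditional_tables(np.asarray(f, dtype=float))[x, ..., gi, :]


def _conditional_tables(f: np.ndarray) -> np.ndarray:
    """P(Gj | Gi, f, x) for all states: shape (3, ..., 3, 3).

    Index order: [x, ...sites, gi, gj].
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    hwe = genotype_prior(f)  # (..., 3)
    zero = np.zeros_like(f)
    one = np.ones_like(f)
    # x = 0: rows all equal to the HWE prior
    c0 = np.broadcast_to(hwe[..., None, :], f.shape + (3, 3)).copy()
    # x = 1: one allele copied IBD, one drawn from the population
    c1 = np.stack(
        [
            np.stack([1 - f, f, zero], axis=-1),
            np.stack([(1 - f) / 2, one / 2, f / 2], axis=-1),
            np.stack([zero, 1 - f, f], axis=-1),
        ],
        axis=-2,
    )
    # x = 2: genotypes forced identical
    c2 = np.broadcast_to(np.eye(3), f.shape + (3, 3)).copy()
    return np.stack([c0, c1, c2], axis=0)


def emission_matrix(pair: PairGL, sites: SiteTable) -> np.ndarray:
    """Per-site emission probabilities E[l, x] = P(data_i, data_j | X_l = x).

    Sums the nine genotype pairs: HWE prior for individual i, the IBD-state
    conditional for individual j, weighted by the two genotype-likelihood
    triples.  Scaling any GL row by a positive constant scales the whole
    emission row by the same constant, which the HMM absorbs into its
    log-likelihood offset.
    """
    if len(pair) != len(sites):
        raise ValueError(
            f"pair has {len(pair)} sites but site table has {len(sites)}"
        )
    f = sites.freqA
    prior = genotype_prior(f)  # (L, 3)
    cond = _conditional_tables(f)  # (3, L, 3, 3)
    wi = prior * pair.gl_i  # (L, 3): P(Gi|f) * P(Di|Gi)
    e = np.einsum("lg,xlgh,lh->lx", wi, cond, pair.gl_j)
    return np.ascontiguousarray(e)
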