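"""Synthetic data generator for the pairwise IBD model.

Simulates, in order: an IBD state path from the CTMC along a grid of sites;
genotypes for the pair (Hardy-Weinberg for the first individual, the
IBD-state conditional for the second); and sequencing data as Poisson read
depth with symmetric per-base error, from which genotype likelihoods are
computed exactly as a caller would.  The output feeds every layer of the
package, so end-to-end parameter-recovery and decoding-accuracy experiments
need no external data.

A single master seed is expanded into independent substreams for sites,
path, genotypes and reads, so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ibd_model import (
    PairGL,
    RelatednessParams,
    SiteTable,
    build_rate_matrix,
    transition_stack,
)

__all__ = [
    "SimConfig",
    "SimOutput",
    "RELATIONSHIPS",
    "genome_config",
    "simulate",
    "sim_sites",
    "sim_ibd_path",
    "sim_genotypes",
    "sim_reads_gls",
    "write_fixture",
]

#: Canonical relationship classes: expected (k0, k1, k2).
RELATIONSHIPS: dict[str, tuple[float, float, float]] = {
    "parent_offspring": (0.0, 1.0, 0.0),
    "full_siblings": (0.25, 0.5, 0.25),
    "half_siblings": (0.5, 0.5, 0.0),
    "first_cousins": (0.75, 0.25, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}

#: Default IBD switch rate for simulated relatives, per Morgan.  Four is the
#: crossover-driven switch rate for a half-sib pair (two meioses) and at the
#: lower end of the range for full siblings; it yields mean IBD tract
#: lengths of 33-50 cM, the scale seen in close relatives.
DEFAULT_ALPHA = 4.0


def genome_config(
    relationship: str,
    depth: float = 4.0,
    seed: int = 0,
    n_sites: int = 20_000,
    err: float = 0.01,
    alpha: float = DEFAULT_ALPHA,
) -> "SimConfig":
    """Study conditions emulating LD-thinned genome-wide human data.

    22 chromosomes carry ``n_sites`` sites at one per 175 kb under a uniform
    1 cM/Mb map — about 35 Morgans in total, the genetic length of the human
    autosomes, at the marker density left after distance thinning.  The IBD
    switch rate defaults to :data:`DEFAULT_ALPHA`.
    """
    if relationship not in RELATIONSHIPS:
        raise KeyError(
            f"unknown relationship {relationship!r}; choose from {sorted(RELATIONSHIPS)}"
        )
    k = RELATIONSHIPS[relationship]
    return SimConfig(
        params=RelatednessParams.from_k(np.asarray(k), alpha).floored(),
        n_sites=n_sites,
        n_chrom=22,
        spacing_bp=175_000,
        cm_per_mb=1.0,
        depth=depth,
        err=err,
        seed=seed,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated pair.

    Defaults give one chromosome with a site every 5 kb under a uniform
    1 cM/Mb map, i.e. 20 000 sites span one Morgan; ``n_chrom`` splits the
    sites into independent chromosomes of that same density.  Frequencies
    are drawn uniformly from ``freq_range``; ``depth`` is the mean Poisson
    coverage per site and individual and ``err`` the per-base error rate.
    """

    params: RelatednessParams
    n_sites: int = 20_000
    n_chrom: int = 1
    spacing_bp: int = 5_000
    cm_per_mb: float = 1.0
    freq_range: tuple[float, float] = (0.05, 0.95)
    depth: float = 4.0
    err: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 1 <= self.n_chrom <= self.n_sites:
            raise ValueError("n_chrom must lie in [1, n_sites]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.err < 0.5:
            raise ValueError("err must lie in [0, 0.5)")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must lie strictly inside (0, 1)")


@dataclass
class SimOutput:
    """Everything the simulator knows about one pair, aligned to L sites."""

    truth_path: np.ndarray
    gi: np.ndarray
    gj: np.ndarray
    counts_i: np.ndarray  # (L, 2): reads carrying allele A, total coverage
    counts_j: np.ndarray
    pair: PairGL
    sites: SiteTable
    freqs: np.ndarray
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _substreams(seed: int, n: int = 4):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sim_sites(config: SimConfig, rng: np.random.Generator) -> SiteTable:
    """Evenly spaced sites on ``n_chrom`` chromosomes with uniform frequencies."""
    n = config.n_sites
    base = n // config.n_chrom
    counts = [base + (1 if c < n % config.n_chrom else 0) for c in range(config.n_chrom)]
    chrom = np.concatenate(
        [np.repeat(f"chr{c + 1}", m) for c, m in enumerate(counts)]
    )
    pos = np.concatenate(
        [(np.arange(m, dtype=np.int64) + 1) * config.spacing_bp for m in counts]
    )
    lo, hi = config.freq_range
    freqs = rng.uniform(lo, hi, size=n)
    return SiteTable.from_positions(chrom, pos, freqs, cm_per_mb=config.cm_per_mb)


def sim_ibd_path(
    params: RelatednessParams, sites: SiteTable, rng: np.random.Generator
) -> np.ndarray:
    """Sample an IBD state path: stationary start per chromosome, CTMC steps.

    The first site of each chromosome draws from (k0, k1, k2); each later
    site draws from the transition row for its genetic distance to the
    previous site, so the marginal state distribution stays stationary.
    """
    p = params.floored()
    q = build_rate_matrix(p)
    trans = transition_stack(q, sites.dist_prev, sites.new_chrom)
    cum = np.cumsum(trans, axis=2)
    cum_pi = np.cumsum(p.k)
    u = rng.random(len(sites))
    path = np.empty(len(sites), dtype=np.int8)
    for l in range(len(sites)):
        row = cum_pi if sites.new_chrom[l] else cum[l, path[l - 1]]
        path[l] = np.searchsorted(row, u[l], side="right")
    return np.minimum(path, 2)


def sim_genotypes(
    truth_path: np.ndarray, freqs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype pair per site given the IBD state.

    Individual i is a Hardy-Weinberg draw (Binomial(2, f) copies of allele
    A); individual j copies 0, 1 or 2 of i's alleles IBD according to the
    state, filling the remainder with fresh population draws.
    """
    truth_path = np.asarray(truth_path)
    freqs = np.asarray(freqs, dtype=float)
    n = len(truth_path)
    gi = rng.binomial(2, freqs).astype(np.int8)
    # allele shared IBD when x = 1: a uniformly chosen allele of gi
    shared = np.where(
        gi == 1, rng.integers(0, 2, size=n), (gi // 2)
    ).astype(np.int8)
    fresh = rng.binomial(1, freqs).astype(np.int8)
    gj_hwe = rng.binomial(2, freqs).astype(np.int8)
    gj = np.where(
        truth_path == 0, gj_hwe, np.where(truth_path == 2, gi, shared + fresh)
    ).astype(np.int8)
    return gi, gj


def sim_reads_gls(
    genotypes: np.ndarray,
    depth: float,
    err: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Reads and genotype likelihoods for one individual.

    Coverage is Poisson(depth); each read reports allele A with probability
    1 - err, 1/2 or err for genotypes 2, 1, 0.  With a reads carrying A out
    of c, the likelihood of genotype g is p_g^a (1 - p_g)^(c - a) up to the
    shared binomial coefficient; triples are scaled to max 1 and sites with
    zero coverage are uninformative (1, 1, 1).
    """
    g = np.asarray(genotypes)
    n = len(g)
    c = rng.poisson(depth, size=n)
    p_true = np.array([err, 0.5, 1.0 - err])[g]
    a = rng.binomial(c, p_true)
    p_g = np.array([err, 0.5, 1.0 - err])  # P(read shows A | genotype)
    with np.errstate(divide="ignore"):
        logp = np.log(p_g)[None, :]
        log1mp = np.log(1.0 - p_g)[None, :]
    # log-space for safety at high depth; 0 * log(0) counts as 0 (err = 0)
    na = a[:, None].astype(float)
    nr = (c - a)[:, None].astype(float)
    with np.errstate(invalid="ignore"):
        loggl = np.where(na == 0, 0.0, na * logp) + np.where(nr == 0, 0.0, nr * log1mp)
    loggl -= loggl.max(axis=1, keepdims=True)
    gl = np.exp(loggl)
    gl[c == 0] = 1.0
    counts = np.stack([a, c], axis=1)
    return gl, counts


def simulate(config: SimConfig) -> SimOutput:
    """Run the full generative model and return all layers."""
    rng_sites, rng_path, rng_geno, rng_reads = _substreams(config.seed)
    sites = sim_sites(config, rng_sites)
    path = sim_ibd_path(config.params, sites, rng_path)
    gi, gj = sim_genotypes(path, sites.freqA, rng_geno)
    gl_i, counts_i = sim_reads_gls(gi, config.depth, config.err, rng_reads)
    gl_j, counts_j = sim_reads_gls(gj, config.depth, config.err, rng_reads)
    return SimOutput(
        truth_path=path,
        gi=gi,
        gj=gj,
        counts_i=counts_i,
        counts_j=counts_j,
        pair=PairGL(gl_i, gl_j),
        sites=sites,
        freqs=sites.freqA,
        config=config,
    )


def write_fixture(sim: SimOutput, prefix) -> dict:
    """Write a simulated pair as beagle + frequency + truth-BED files.

    Gives black-box tests and command-line runs a complete, self-contained
    input set; returns the written paths.
    """
    from .io_formats import BeagleDataset, write_beagle, write_freqs
    from .segments import call_segments_viterbi

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(sim.sites)
    markers = np.array(
        [f"{c}_{p}" for c, p in zip(sim.sites.chrom, sim.sites.pos)]
    )
    ds = BeagleDataset(
        markers=markers,
        allele1=sim.sites.alleleA.copy(),
        allele2=sim.sites.allelea.copy(),
        gls=np.stack([sim.pair.gl_i, sim.pair.gl_j]),
        chrom=sim.sites.chrom.copy(),
        pos=sim.sites.pos.copy(),
    )
    paths = {
        "beagle": Path(str(prefix) + ".beagle.gz"),
        "freqs": Path(str(prefix) + ".freqs"),
        "truth": Path(str(prefix) + ".truth.bed"),
    }
    write_beagle(paths["beagle"], ds)
    write_freqs(paths["freqs"], sim.freqs)
    with open(paths["truth"], "w") as fh:
        for seg in call_segments_viterbi(sim.truth_path, sim.sites):
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state}\t{seg.n_sites}\n")
    return paths
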