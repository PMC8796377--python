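import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sites(dists, chroms=None, freqs=None):
    """Small SiteTable from explicit genetic distances (Morgans)."""
    from ibdpair import SiteTable

    dists = np.asarray(dists, dtype=float)
    n = len(dists)
    if chroms is None:
        chroms = np.repeat("chr1", n)
    chroms = np.asarray(chroms)
    new_chrom = np.ones(n, dtype=bool)
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    d = dists.copy()
    d[new_chrom] = 0.0
    pos = np.zeros(n, dtype=np.int64)
    here = 0
    for i in range(n):
        here = 100 if new_chrom[i] else here + max(int(d[i] * 1e8), 1)
        pos[i] = here
    if freqs is None:
        freqs = np.full(n, 0.5)
    return SiteTable(
        chroms, pos, np.zeros(n, np.int8), np.ones(n, np.int8),
        np.asarray(freqs, float), d, new_chrom,
    )


def random_instance(rng, max_sites=6, multi_chrom=True):
    """Random tiny HMM instance: emissions, sites, parameters."""
    from ibdpair import RelatednessParams

    L = int(rng.integers(1, max_sites + 1))
    k = rng.dirichlet(np.ones(3))
    alpha = float(np.exp(rng.uniform(np.log(0.05), np.log(30.0))))
    params = RelatednessParams.from_k(k, alpha).floored()
    dists = rng.uniform(0.0, 0.5, size=L)
    if multi_chrom and L >= 3 and rng.random() < 0.4:
        split = int(rng.integers(1, L))
        chroms = np.array(["chr1"] * split + ["chr2"] * (L - split))
    else:
        chroms = None
    sites = make_sites(dists, chroms=chroms)
    e = rng.uniform(0.01, 1.0, size=(L, 3))
    return e, sites, params


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
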