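"""HMM inference checked against exhaustive path enumeration and its
invariances (scaling, pair symmetry, chromosome independence)."""

import numpy as np
import pytest

from ibdpair import (
    PairGL,
    RelatednessParams,
    emission_matrix,
    log_likelihood,
    posterior_decode,
    viterbi,
)
from ibdpair.hmm_engine import path_log_probability

from conftest import make_sites, random_instance
from _oracles import enumerate_paths


def test_matches_enumeration_on_random_instances(rng):
    """Forward/backward/Viterbi agree with the 3^L brute-force sum."""
    for _ in range(40):
        e, sites, params = random_instance(rng)
        ll_ref, post_ref, path_ref, logp_ref = enumerate_paths(
            e, sites.dist_prev, sites.new_chrom, params.k, params.alpha
        )
        assert log_likelihood(e, sites, params) == pytest.approx(ll_ref, rel=1e-8)
        dec = posterior_decode(e, sites, params)
        np.testing.assert_allclose(dec.posteriors, post_ref, rtol=1e-8, atol=1e-10)
        vit = viterbi(e, sites, params)
        logp = path_log_probability(e, sites, params, vit.viterbi_path)
        assert logp == pytest.approx(logp_ref, rel=1e-8)


def test_single_site_closed_forms(rng):
    params = RelatednessParams(0.2, 0.5, 0.3, 1.0)
    e = np.array([[0.3, 0.9, 0.1]])
    sites = make_sites([0.0])
    marginal = params.k @ e[0]
    assert log_likelihood(e, sites, params) == pytest.approx(np.log(marginal))
    dec = posterior_decode(e, sites, params)
    np.testing.assert_allclose(
        dec.posteriors[0], params.k * e[0] / marginal, rtol=1e-12
    )


def test_uninformative_emissions(rng):
    """All-ones emissions: total probability 1; distant sites sit at R."""
    params = RelatednessParams(0.2, 0.5, 0.3, 1.0)
    L = 20
    e = np.ones((L, 3))
    sites = make_sites(np.full(L, 100.0))  # alpha*d >> 1: relaxed to stationarity
    assert log_likelihood(e, sites, params) == pytest.approx(0.0, abs=1e-12)
    dec = posterior_decode(e, sites, params)
    np.testing.assert_allclose(
        dec.posteriors, np.tile(params.k, (L, 1)), atol=1e-9
    )
    # prior and self-transition both favour the heaviest state
    vit = viterbi(e, sites, params)
    assert (vit.viterbi_path == 1).all()


def test_viterbi_ties_break_to_lowest_state():
    # exact three-way ties per site: uniform prior, uniform emissions,
    # each site on its own chromosome so no transitions perturb the scores
    params = RelatednessParams(1 / 3, 1 / 3, 1 / 3, 1.0)
    L = 5
    e = np.ones((L, 3))
    sites = make_sites(np.zeros(L), chroms=np.array([f"chr{i}" for i in range(L)]))
    vit = viterbi(e, sites, params)
    assert (vit.viterbi_path == 0).all()


def test_forced_path_recovered(rng):
    L = 30
    target = rng.integers(0, 3, size=L)
    e = np.full((L, 3), 1e-30)
    e[np.arange(L), target] = 1.0
    sites = make_sites(rng.uniform(0.001, 0.05, L))
    vit = viterbi(e, sites, RelatednessParams(0.25, 0.5, 0.25, 2.0))
    np.testing.assert_array_equal(vit.viterbi_path, target)


def test_gl_scaling_shifts_loglik_only(rng):
    e, sites, params = random_instance(rng, max_sites=6)
    L = e.shape[0]
    c = rng.uniform(0.1, 10.0, size=L)
    dec = posterior_decode(e, sites, params)
    vit = viterbi(e, sites, params)
    dec2 = posterior_decode(e * c[:, None], sites, params)
    vit2 = viterbi(e * c[:, None], sites, params)
    assert dec2.loglik == pytest.approx(dec.loglik + np.log(c).sum(), rel=1e-10)
    np.testing.assert_allclose(dec2.posteriors, dec.posteriors, rtol=1e-9)
    np.testing.assert_array_equal(vit2.viterbi_path, vit.viterbi_path)


def test_pair_swap_leaves_inference_unchanged(rng):
    L = 60
    sites = make_sites(rng.uniform(0, 0.05, L), freqs=rng.uniform(0.05, 0.95, L))
    pair = PairGL(rng.uniform(0.01, 1, (L, 3)), rng.uniform(0.01, 1, (L, 3)))
    params = RelatednessParams(0.25, 0.5, 0.25, 4.0)
    e1 = emission_matrix(pair, sites)
    e2 = emission_matrix(pair.swapped(), sites)
    d1, d2 = posterior_decode(e1, sites, params), posterior_decode(e2, sites, params)
    assert d1.loglik == pytest.approx(d2.loglik, rel=1e-12)
    np.testing.assert_allclose(d1.posteriors, d2.posteriors, rtol=1e-10)
    np.testing.assert_array_equal(
        viterbi(e1, sites, params).viterbi_path,
        viterbi(e2, sites, params).viterbi_path,
    )


def test_chromosomes_are_independent(rng):
    """Two-chromosome loglik equals the sum of single-chromosome logliks."""
    params = RelatednessParams(0.3, 0.5, 0.2, 3.0)
    La, Lb = 5, 4
    ea = rng.uniform(0.01, 1, (La, 3))
    eb = rng.uniform(0.01, 1, (Lb, 3))
    da = rng.uniform(0, 0.2, La)
    db = rng.uniform(0, 0.2, Lb)
    joint = make_sites(
        np.concatenate([da, db]),
        chroms=np.array(["chr1"] * La + ["chr2"] * Lb),
    )
    ll = log_likelihood(np.vstack([ea, eb]), joint, params)
    ll_parts = log_likelihood(ea, make_sites(da), params) + log_likelihood(
        eb, make_sites(db), params
    )
    assert ll == pytest.approx(ll_parts, rel=1e-12)


def test_posterior_rows_normalised_and_scale_identity(rng):
    e, sites, params = random_instance(rng, max_sites=6)
    dec = posterior_decode(e, sites, params)
    np.testing.assert_allclose(dec.posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert dec.loglik == pytest.approx(dec.scale_log.sum(), rel=1e-12)


def test_sharper_emissions_raise_truth_path_posterior(rng):
    """Monotone information: sharpening emissions toward a fixed truth path
    never lowers that path's mean posterior."""
    L = 50
    truth = rng.integers(0, 3, size=L)
    sites = make_sites(rng.uniform(0.001, 0.02, L))
    params = RelatednessParams(0.25, 0.5, 0.25, 4.0)
    prev = -np.inf
    for sharp in (1.0, 2.0, 5.0, 20.0):
        e = np.ones((L, 3))
        e[np.arange(L), truth] = sharp
        dec = posterior_decode(e, sites, params)
        cur = dec.posteriors[np.arange(L), truth].mean()
        assert cur >= prev - 1e-12
        prev = cur


def test_structural_errors():
    params = RelatednessParams(0.25, 0.5, 0.25, 1.0)
    with pytest.raises(ValueError):
        log_likelihood(np.empty((0, 3)), make_sites([]), params)
    with pytest.raises(ValueError):
        log_likelihood(np.full((2, 3), np.nan), make_sites([0.0, 0.1]), params)
    with pytest.raises(ValueError):
        log_likelihood(np.ones((3, 3)), make_sites([0.0, 0.1]), params)
    with pytest.raises(FloatingPointError, match="site 1"):
        log_likelihood(
            np.array([[1.0, 1, 1], [0.0, 0, 0], [1, 1, 1]]),
            make_sites([0.0, 0.1, 0.1]),
            params,
        )
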