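"""Unit and property tests for the CTMC rate/transition structure and the
genotype-pair emission model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ibdpair import (
    PairGL,
    RelatednessParams,
    build_rate_matrix,
    conditional_genotype_prob,
    emission_matrix,
    genotype_prior,
    transition_matrix,
)
from ibdpair.ibd_model import _conditional_tables, transition_stack

from conftest import make_sites
from _oracles import taylor_expm


@st.composite
def valid_params(draw):
    raw = np.array([draw(st.floats(0.01, 10.0)) for _ in range(3)])
    k = raw / raw.sum()
    alpha = draw(st.floats(0.01, 50.0))
    return RelatednessParams.from_k(k, alpha)


class TestRateMatrix:
    def test_printed_entries(self):
        q = build_rate_matrix(RelatednessParams(0.25, 0.5, 0.25, 1.0)).q
        np.testing.assert_allclose(q[0], [-0.5, 0.5, 0.0])
        np.testing.assert_allclose(q[1], [0.25, -0.5, 0.25])
        np.testing.assert_allclose(q[2], [0.0, 0.5, -0.5])

    @given(valid_params())
    def test_structure_and_stationarity(self, params):
        q = build_rate_matrix(params).q
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert q[0, 2] == 0.0 and q[2, 0] == 0.0
        off = q[~np.eye(3, dtype=bool)]
        assert (off >= 0).all()
        np.testing.assert_allclose(params.k @ q, 0.0, atol=1e-10)

    def test_rates_scale_linearly_in_alpha(self):
        k = (0.3, 0.5, 0.2)
        q1 = build_rate_matrix(RelatednessParams(*k, 1.0)).q
        q2 = build_rate_matrix(RelatednessParams(*k, 1e-9)).q
        np.testing.assert_allclose(q2, q1 * 1e-9)
        np.testing.assert_allclose(q2, 0.0, atol=1e-8)

    @pytest.mark.parametrize(
        "k, alpha",
        [((0.5, 0.5, 0.1), 1.0), ((-0.1, 0.6, 0.5), 1.0),
         ((0.25, 0.5, 0.25), 0.0), ((0.25, 0.5, 0.25), -2.0)],
    )
    def test_invalid_parameters_rejected(self, k, alpha):
        with pytest.raises(ValueError):
            build_rate_matrix(RelatednessParams(*k, alpha))


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        q = build_rate_matrix(RelatednessParams(0.25, 0.5, 0.25, 1.0))
        np.testing.assert_allclose(transition_matrix(q, 0.0), np.eye(3), atol=1e-12)

    def test_long_distance_reaches_stationarity(self):
        params = RelatednessParams(0.25, 0.5, 0.25, 1.0)
        t = transition_matrix(build_rate_matrix(params), 60.0)
        for row in t:
            np.testing.assert_allclose(row, params.k, atol=1e-8)

    def test_matches_taylor_series_oracle(self):
        params = RelatednessParams(0.25, 0.5, 0.25, 1.0)
        q = build_rate_matrix(params)
        np.testing.assert_allclose(
            transition_matrix(q, 0.1), taylor_expm(q.q, 0.1), atol=1e-10
        )

    @given(valid_params(), st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_semigroup_and_stationarity(self, params, d1, d2):
        q = build_rate_matrix(params)
        t1, t2, t12 = (transition_matrix(q, d) for d in (d1, d2, d1 + d2))
        np.testing.assert_allclose(t1 @ t2, t12, atol=1e-10)
        np.testing.assert_allclose(params.k @ t1, params.k, atol=1e-10)
        np.testing.assert_allclose(t1.sum(axis=1), 1.0, atol=1e-12)
        assert (t1 >= 0).all() and (t1 <= 1).all()

    def test_negative_distance_rejected(self):
        q = build_rate_matrix(RelatednessParams(0.25, 0.5, 0.25, 1.0))
        with pytest.raises(ValueError):
            transition_matrix(q, -0.1)

    def test_degenerate_parent_offspring_params_still_valid(self):
        # k0 = k2 = 0 floors to the simplex interior; exponential stays stochastic
        params = RelatednessParams(0.0, 1.0, 0.0, 4.0).floored()
        q = build_rate_matrix(params)
        t = transition_matrix(q, 0.02)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)
        assert t[1, 1] > 0.999

    def test_stack_deduplicates_and_marks_chromosome_starts(self):
        params = RelatednessParams(0.25, 0.5, 0.25, 2.0)
        q = build_rate_matrix(params)
        dists = np.array([0.0, 0.01, 0.01, 0.0, 0.02])
        new = np.array([True, False, False, True, False])
        stack = transition_stack(q, dists, new)
        np.testing.assert_allclose(stack[1], stack[2])
        np.testing.assert_allclose(stack[0], np.eye(3))
        np.testing.assert_allclose(stack[3], np.eye(3))
        np.testing.assert_allclose(stack[1], transition_matrix(q, 0.01), atol=1e-12)


class TestGenotypePriors:
    def test_hardy_weinberg_values(self):
        np.testing.assert_allclose(genotype_prior(0.5), [0.25, 0.5, 0.25])
        np.testing.assert_allclose(genotype_prior(0.2), [0.64, 0.32, 0.04])
        np.testing.assert_allclose(
            genotype_prior(1 - 1e-9), [0, 0, 1], atol=1e-8
        )

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.4])
    def test_frequency_domain_enforced(self, f):
        with pytest.raises(ValueError):
            genotype_prior(f)

    def test_conditional_point_mass_when_two_ibd(self):
        for gi in (0, 1, 2):
            expected = np.zeros(3)
            expected[gi] = 1.0
            np.testing.assert_allclose(
                conditional_genotype_prob(gi, 0.3, 2), expected
            )

    def test_conditional_reduces_to_hwe_when_zero_ibd(self):
        for gi in (0, 1, 2):
            np.testing.assert_allclose(
                conditional_genotype_prob(gi, 0.5, 0), [0.25, 0.5, 0.25]
            )

    def test_conditional_one_ibd_heterozygote(self):
        # shared allele is A or a with prob 1/2 each; free allele ~ f
        f = 0.3
        np.testing.assert_allclose(
            conditional_genotype_prob(1, f, 1), [0.35, 0.5, 0.15]
        )
        np.testing.assert_allclose(
            conditional_genotype_prob(0, f, 1), [1 - f, f, 0.0]
        )
        np.testing.assert_allclose(
            conditional_genotype_prob(2, f, 1), [0.0, 1 - f, f]
        )

    @pytest.mark.parametrize("gi,x", [(3, 0), (-1, 1), (0, 3), (1, -1)])
    def test_conditional_domain_errors(self, gi, x):
        with pytest.raises(ValueError):
            conditional_genotype_prob(gi, 0.5, x)

    def test_joint_distribution_normalised_and_symmetric(self):
        # sum over the 9 genotype pairs is 1; joint symmetric under i <-> j
        for f in np.linspace(0.02, 0.98, 25):
            prior = genotype_prior(f)
            cond = _conditional_tables(np.asarray(f))
            for x in range(3):
                joint = prior[:, None] * cond[x]
                assert abs(joint.sum() - 1.0) < 1e-12
                np.testing.assert_allclose(joint, joint.T, atol=1e-12)


class TestEmissions:
    def test_uninformative_gls_emit_one(self, rng):
        L = 8
        sites = make_sites(rng.uniform(0, 0.1, L), freqs=rng.uniform(0.1, 0.9, L))
        pair = PairGL(np.ones((L, 3)), np.ones((L, 3)))
        np.testing.assert_allclose(emission_matrix(pair, sites), 1.0, atol=1e-12)

    def test_certain_homozygous_pair(self):
        # both certainly AA at f = 0.5: the 9-term sum collapses to one pair
        sites = make_sites([0.0], freqs=[0.5])
        pair = PairGL(np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, 1.0]]))
        e = emission_matrix(pair, sites)
        np.testing.assert_allclose(e[0], [0.0625, 0.125, 0.25], atol=1e-12)

    def test_swap_and_rescaling_invariances(self, rng):
        L = 40
        sites = make_sites(rng.uniform(0, 0.1, L), freqs=rng.uniform(0.05, 0.95, L))
        pair = PairGL(rng.uniform(0.01, 1, (L, 3)), rng.uniform(0.01, 1, (L, 3)))
        e = emission_matrix(pair, sites)
        np.testing.assert_allclose(
            emission_matrix(pair.swapped(), sites), e, rtol=1e-12
        )
        ci = rng.uniform(0.5, 2.0, (L, 1))
        cj = rng.uniform(0.5, 2.0, (L, 1))
        scaled = PairGL(pair.gl_i * ci, pair.gl_j * cj)
        np.testing.assert_allclose(
            emission_matrix(scaled, sites), e * ci * cj, rtol=1e-10
        )

    def test_length_mismatch_rejected(self, rng):
        sites = make_sites([0.0, 0.01])
        pair = PairGL(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError, match="site"):
            emission_matrix(pair, sites)
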