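import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycopoly import digest_model as dm
from glycopoly.measurements import CategoryTable

from conftest import random_balanced_P, random_profile
from oracles import brute_digest_distribution, brute_fragment_counts, \
    enumerate_sequences


def mc_check(sample, yields, n, cap, expected, reps=200_000, batches=10,
             seed=0):
    """Assert a closed form against batched Monte-Carlo within 3 sigma."""
    gs = np.array([
        dm.simulate_digest(sample, yields, n, cap, reps // batches,
                           seed=seed + k).g
        for k in range(batches)
    ])
    mean = gs.mean(axis=0)
    se = gs.std(axis=0, ddof=1) / np.sqrt(batches)
    assert np.all(np.abs(mean - expected) <= 3 * se + 1e-12), \
        (mean - expected) / np.maximum(se, 1e-12)


class TestExpectedFragmentCounts:
    def test_hand_enumerated_example(self):
        # x S U U under an S-preferring enzyme
        q, Q = dm.expected_fragment_counts(
            dm.cut_probs("USUU", (1.0, 0.03)), cap=4)
        np.testing.assert_allclose(q, [0.0609, 0.0582, 0.9409, 0.0],
                                   atol=1e-12)
        assert Q == pytest.approx(1.06, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="SU", min_size=3, max_size=7),
           st.floats(0, 1), st.floats(0, 1), st.integers(2, 6))
    def test_matches_cut_pattern_enumeration(self, seq, cS, cU, cap):
        q, Q = dm.expected_fragment_counts(dm.cut_probs(seq, (cS, cU)), cap)
        q_ref, Q_ref = brute_fragment_counts(seq, (cS, cU), cap)
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        assert Q == pytest.approx(Q_ref, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="SU", min_size=3, max_size=12),
           st.floats(0, 1), st.floats(0, 1))
    def test_cut_counting_identity(self, seq, cS, cU):
        c = dm.cut_probs(seq, (cS, cU))
        q, Q = dm.expected_fragment_counts(c, cap=4)
        assert q.sum() == pytest.approx(c.sum(), abs=1e-12)
        assert Q == pytest.approx(c.sum(), abs=1e-12)

    def test_full_cleavage_gives_only_monomers(self):
        q, Q = dm.expected_fragment_counts(np.ones(9), cap=5)
        assert q[0] == pytest.approx(9.0) and q[1:].sum() == 0

    def test_zero_yields_give_no_counted_fragments(self):
        q, Q = dm.expected_fragment_counts(np.zeros(9), cap=5)
        assert Q == 0.0 and q.sum() == 0.0

    def test_block_version_matches_scalar(self):
        n, yields, cap = 5, (0.8, 0.1), 3
        qb, Qb = dm.expected_fragment_counts_block(
            np.arange(1 << n), n, yields, cap)
        for code, seq in enumerate(enumerate_sequences(n)):
            q, Q = dm.expected_fragment_counts(dm.cut_probs(seq, yields), cap)
            np.testing.assert_allclose(qb[code], q, atol=1e-12)
            assert Qb[code] == pytest.approx(Q, abs=1e-12)


class TestHomogeneousIndependent:
    def test_matches_dense_mixture_oracle(self, bkhs):
        n = 5
        rho_S = bkhs.table.rho[0]
        p = {}
        for seq in enumerate_sequences(n):
            w = 1.0 / 2  # free NRE position
            for ch in seq[1:]:
                w *= rho_S if ch == "S" else 1 - rho_S
            p[seq] = w
        for enz in ("hepI", "hepIII"):
            g_ref = brute_digest_distribution(
                p, bkhs.table.yields_[enz], cap=4)
            g = dm.hi_distribution(bkhs.table, n, enz, cap=4)
            np.testing.assert_allclose(g.g, g_ref, atol=1e-12)

    def test_bkhs_leading_bins(self, bkhs):
        # frozen from the closed form after oracle certification
        g3 = dm.hi_distribution(bkhs.table, 16, "hepIII", 6)
        assert g3.g[0] == pytest.approx(0.877436, abs=1e-6)
        g1 = dm.hi_distribution(bkhs.table, 16, "hepI", 11)
        assert g1.g[0] == pytest.approx(0.217611, abs=1e-6)
        # the observed 0.4676 monomer fraction is far outside this model
        assert abs(bkhs.digest("hepI").probs[0] - g1.g[0]) > 0.2

    def test_certain_cleavage_gives_monomers(self):
        table = CategoryTable(rho=(0.3, 0.7), yields_={"z": (1.0, 1.0)})
        g = dm.hi_distribution(table, 10, "z", 4)
        assert g.g[0] == pytest.approx(1.0)

    def test_monte_carlo_agreement(self, bkhs):
        for enz in ("hepI", "hepIII"):
            cap = bkhs.digest(enz).cap
            mc_check(dm.sample_chains_iid(16, bkhs.table.rho[0]),
                     bkhs.table.yields_[enz], 16, cap,
                     dm.hi_distribution(bkhs.table, 16, enz, cap).g)

    @pytest.mark.parametrize("n", [10, 13, 16, 20])
    @pytest.mark.parametrize("enzyme", ["hepI", "hepIII"])
    def test_log_linearity(self, bkhs, n, enzyme):
        """log g(l) over l = 1..n-2 is near-linear for the measured yields."""
        g = dm.hi_distribution(bkhs.table, n, enzyme, cap=n - 1)
        assert dm.log_linear_r2(g.g[: n - 2]) >= 0.99


class TestHomogeneousMarkov:
    def test_independence_embeds(self, bkhs):
        P = np.tile(bkhs.table.rho, (2, 1))
        for enz in ("hepI", "hepIII"):
            g = dm.hc_distribution(P, bkhs.table, 16, enz, 8)
            gi = dm.hi_distribution(bkhs.table, 16, enz, 8)
            np.testing.assert_allclose(g.g, gi.g, atol=1e-12)

    def test_identity_transitions_two_sequence_mixture(self, bkhs):
        # P = I keeps chains all-S or all-U below the non-reducing end
        n, cap = 6, 4
        rho_S = bkhs.table.rho[0]
        for enz in ("hepI", "hepIII"):
            p = {"U" + "S" * (n - 1): rho_S, "U" + "U" * (n - 1): 1 - rho_S}
            g_ref = brute_digest_distribution(p, bkhs.table.yields_[enz], cap)
            g = dm.hc_distribution(np.eye(2), bkhs.table, n, enz, cap)
            np.testing.assert_allclose(g.g, g_ref, atol=1e-12)

    def test_matches_dense_oracle_for_random_P(self, bkhs, rng):
        n, cap = 6, 4
        rho = bkhs.table.rho
        P = random_balanced_P(rng, rho)
        p = {}
        for seq in enumerate_sequences(n):
            w = 0.5 * (rho[0] if seq[1] == "S" else rho[1])
            for a, b in zip(seq[1:], seq[2:]):
                w *= P["SU".index(a), "SU".index(b)]
            p[seq] = w
        for enz in ("hepI", "hepIII"):
            g_ref = brute_digest_distribution(p, bkhs.table.yields_[enz], cap)
            g = dm.hc_distribution(P, bkhs.table, n, enz, cap)
            np.testing.assert_allclose(g.g, g_ref, atol=1e-12)

    def test_monte_carlo_agreement(self, bkhs, rng):
        P = random_balanced_P(rng, bkhs.table.rho)
        tr = np.broadcast_to(P, (14, 2, 2))
        for enz in ("hepI", "hepIII"):
            cap = bkhs.digest(enz).cap
            g = dm.hc_distribution(P, bkhs.table, 16, enz, cap)
            mc_check(dm.sample_chains_markov(np.array(bkhs.table.rho), tr, 16),
                     bkhs.table.yields_[enz], 16, cap, g.g)

    def test_row_stochasticity_enforced(self, bkhs):
        P = np.array([[0.7, 0.4], [0.1, 0.9]])
        with pytest.raises(ValueError, match="sum to 1"):
            dm.hc_distribution(P, bkhs.table, 16, "hepI", 11)


class TestNonhomogeneousIndependent:
    def test_homogeneous_limit(self, bkhs):
        gamma = np.tile(bkhs.table.rho, (16, 1))
        for enz in ("hepI", "hepIII"):
            g = dm.ni_distribution(gamma, bkhs.table, 16, enz, 9)
            gi = dm.hi_distribution(bkhs.table, 16, enz, 9)
            np.testing.assert_allclose(g.g, gi.g, atol=1e-12)

    def test_matches_dense_oracle_for_random_profile(self, bkhs, rng):
        n, cap = 6, 4
        gamma = random_profile(rng, bkhs.table.rho, n)
        p = {}
        for seq in enumerate_sequences(n):
            w = 0.5
            for i, ch in enumerate(seq[1:], start=2):
                w *= gamma[i - 1, 0] if ch == "S" else gamma[i - 1, 1]
            p[seq] = w
        for enz in ("hepI", "hepIII"):
            g_ref = brute_digest_distribution(p, bkhs.table.yields_[enz], cap)
            g = dm.ni_distribution(gamma, bkhs.table, n, enz, cap)
            np.testing.assert_allclose(g.g, g_ref, atol=1e-12)

    def test_comb_profile_by_direct_products(self):
        # cut probability 1 at even positions, 0 at odd ones; rho must match
        # the profile mean (4 of the 7 constrained positions are S)
        n = 8
        table = CategoryTable(rho=(4 / 7, 3 / 7), yields_={"z": (1.0, 0.0)})
        gamma_S = np.array([0.5] + [1.0 if i % 2 == 0 else 0.0
                                    for i in range(2, n + 1)])
        gamma = np.column_stack([gamma_S, 1 - gamma_S])
        g = dm.ni_distribution(gamma, table, n, "z", cap=4)
        # cuts at 2,4,6,8 -> counted fragments (2,3),(4,5),(6,7),(8): three
        # dimers and one terminal monomer
        np.testing.assert_allclose(g.g, [0.25, 0.75, 0, 0], atol=1e-12)

    def test_monte_carlo_agreement(self, bkhs, rng):
        gamma = random_profile(rng, bkhs.table.rho, 16)
        for enz in ("hepI", "hepIII"):
            cap = bkhs.digest(enz).cap
            g = dm.ni_distribution(gamma, bkhs.table, 16, enz, cap)
            mc_check(dm.sample_chains_profile(gamma[:, 0]),
                     bkhs.table.yields_[enz], 16, cap, g.g)

    def test_invalid_rows_rejected(self, bkhs):
        gamma = np.tile(bkhs.table.rho, (16, 1))
        gamma[4, 0] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            dm.ni_distribution(gamma, bkhs.table, 16, "hepI", 11)


class TestSimulator:
    def test_full_cleavage_all_monomers(self):
        g = dm.simulate_digest(dm.sample_chains_iid(10, 0.5), (1.0, 1.0),
                               10, 5, 5000, seed=3)
        assert g.g[0] == 1.0

    def test_seed_reproducibility(self, bkhs):
        args = (dm.sample_chains_iid(16, 0.2), bkhs.table.yields_["hepI"],
                16, 11, 20_000)
        g1 = dm.simulate_digest(*args, seed=11)
        g2 = dm.simulate_digest(*args, seed=11)
        np.testing.assert_array_equal(g1.g, g2.g)

    def test_explicit_p_sampler_matches_model(self, bkhs):
        # point mass on one species: empirical distribution ~ q(s,.)/Q(s)
        n, cap = 6, 4
        p = np.zeros(1 << n)
        code = 0b010110
        p[code] = 1.0
        seq = "".join("S" if (code >> (n - i)) & 1 else "U"
                      for i in range(1, n + 1))
        q, Q = dm.expected_fragment_counts(
            dm.cut_probs(seq, bkhs.table.yields_["hepI"]), cap)
        mc_check(dm.sample_chains_from_p(p, n), bkhs.table.yields_["hepI"],
                 n, cap, q / Q, reps=100_000)

    def test_unnormalized_p_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            dm.sample_chains_from_p(np.full(4, 0.3), 2)


class TestLengthPooling:
    def test_single_length_is_identity(self, bkhs):
        g = dm.hi_distribution(bkhs.table, 12, "hepI", 6)
        pooled = dm.mix_over_lengths([g], [11 * 0.16], [1.0])
        np.testing.assert_allclose(pooled.g, g.g, atol=1e-15)

    def test_counts_pooled_before_normalizing(self, bkhs):
        # two lengths, equal chain weights: the longer length contributes
        # proportionally to its expected fragment count, not 50/50
        table = bkhs.table
        enz = "hepIII"
        cbar = table.mean_yield(enz)
        gs = [dm.hi_distribution(table, n, enz, 6) for n in (8, 16)]
        alphas = [(n - 1) * cbar for n in (8, 16)]
        pooled = dm.mix_over_lengths(gs, alphas, [0.5, 0.5])
        expected = (alphas[0] * gs[0].g + alphas[1] * gs[1].g) / sum(alphas)
        np.testing.assert_allclose(pooled.g, expected, atol=1e-15)
        naive = 0.5 * gs[0].g + 0.5 * gs[1].g
        assert np.abs(pooled.g - naive).max() > 1e-4
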