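import numpy as np
import pytest

from glycopoly import constraint_system as csys
from glycopoly import length_mixture as lm
from glycopoly import polytope_analysis as pa
from glycopoly.digest_model import mix_over_lengths, ni_distribution
from glycopoly.measurements import CategoryTable, DigestDistribution, \
    MeasurementSet
from glycopoly.species_space import build_space

from oracles import brute_fragment_counts, enumerate_sequences


class TestGaussianLengthDistribution:
    def test_zero_sigma_is_point_mass(self):
        w = lm.gaussian_length_distribution(16, 0.0, 10, 20)
        assert w.w[w.lengths.index(16)] == 1.0
        assert w.w.sum() == 1.0

    @pytest.mark.parametrize("sigma", [1.5, 3.5])
    def test_projected_distribution_satisfies_constraints(self, sigma):
        w = lm.gaussian_length_distribution(16, sigma, 10, 20)
        assert w.w.min() >= 0
        assert w.w.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(np.dot(w.lengths, w.w)) == pytest.approx(16.0, abs=1e-9)

    def test_mass_concentrates_near_the_mean(self):
        # bins are [n, n+1) integrals, so exact mirror symmetry is not
        # expected; the mode must sit at the mean and tails must decay
        w = lm.gaussian_length_distribution(16, 2.0, 10, 22)
        mode = w.lengths[int(np.argmax(w.w))]
        assert mode in (15, 16)
        assert w.w[0] < w.w.max() / 5 and w.w[-1] < w.w.max() / 5

    def test_mean_outside_range_rejected(self):
        with pytest.raises(ValueError):
            lm.gaussian_length_distribution(9, 1.0, 10, 20)


def mixture_ni_measurements(table, gamma_by_n, w):
    """Exact pooled measurements for per-length independent-profile truths."""
    lengths = sorted(gamma_by_n)
    digests = []
    for enz, (cS, cU) in table.yields_.items():
        cap = 6
        dists, alphas = [], []
        for n in lengths:
            g = gamma_by_n[n]
            gamma = np.column_stack([g, 1 - g])
            tab_n = CategoryTable(rho=(g[1:].mean(), 1 - g[1:].mean()),
                                  yields_=table.yields_)
            dists.append(ni_distribution(gamma, tab_n, n, enz, cap))
            alphas.append((n - 1) * tab_n.mean_yield(enz))
        pooled = mix_over_lengths(dists, alphas, [w[n] for n in lengths])
        digests.append(DigestDistribution(enzyme=enz, cap=cap, probs=pooled.g))
    # overall rho: abundance-weighted disaccharide count fractions
    num = sum(w[n] * gamma_by_n[n][1:].sum() for n in lengths)
    den = sum(w[n] * (len(gamma_by_n[n]) - 1) for n in lengths)
    rho_S = num / den
    mean_n = sum(w[n] * n for n in lengths)
    return MeasurementSet(
        table=CategoryTable(rho=(rho_S, 1 - rho_S), yields_=table.yields_),
        digests=tuple(digests),
        mean_length=int(round(mean_n)),
        length_range=(lengths[0], lengths[-1]),
    )


@pytest.fixture(scope="module")
def small_mixture(bkhs):
    rng = np.random.default_rng(5)
    lengths = (4, 5, 6)
    w = {4: 0.25, 5: 0.5, 6: 0.25}
    gamma_by_n = {n: rng.uniform(0.1, 0.5, n) for n in lengths}
    ms = mixture_ni_measurements(bkhs.table, gamma_by_n, w)
    return ms, gamma_by_n, w


class TestMixturePolytope:
    def test_exact_mixture_measurements_are_feasible(self, small_mixture):
        ms, gamma_by_n, w = small_mixture
        space = build_space(sorted(w))
        wvec = np.array([w[n] for n in sorted(w)])
        cs = csys.assemble(ms, space, w=wvec)
        assert pa.infeasibility(cs) <= 1e-8

    def test_per_length_composition_identities(self, small_mixture):
        ms, gamma_by_n, w = small_mixture
        space = build_space(sorted(w))
        wvec = np.array([w[n] for n in sorted(w)])
        cs = csys.assemble(ms, space, w=wvec)
        sol = pa.solve_maxent(cs)
        table = lm.per_length_composition(sol.p, space)
        np.testing.assert_allclose(table["mass"], wvec, atol=1e-7)
        # disaccharide-weighted average recovers the overall composition
        weights = table["mass"] * (np.array(sorted(w)) - 1)
        avg = float((table["S_fraction"] * weights).sum() / weights.sum())
        assert avg == pytest.approx(ms.table.rho[0], abs=1e-6)

    def test_homogeneous_truth_gives_flat_per_length_composition(self, bkhs):
        rho_S = bkhs.table.rho[0]
        lengths = (4, 5, 6)
        w = {4: 0.25, 5: 0.5, 6: 0.25}
        gamma_by_n = {n: np.full(n, rho_S) for n in lengths}
        ms = mixture_ni_measurements(bkhs.table, gamma_by_n, w)
        space = build_space(lengths)
        # the homogeneous product model per block, scaled by w
        p = np.zeros(space.total)
        for n in lengths:
            start, stop = space.block(n)
            counts = space.s_counts(n)
            p[start:stop] = w[n] * 0.5 * rho_S**counts \
                * (1 - rho_S) ** (n - 1 - counts)
        table = lm.per_length_composition(p, space)
        np.testing.assert_allclose(table["S_fraction"], rho_S, atol=1e-12)

    def test_zero_mass_length_reported_as_nan(self):
        space = build_space([2, 3])
        p = np.zeros(space.total)
        p[space.block(3)[0]] = 1.0
        table = lm.per_length_composition(p, space)
        assert np.isnan(table.loc[table["n"] == 2, "S_fraction"]).all()


class TestEqualCompositionFeasibility:
    def test_point_mass_reduces_to_single_length_verdict(self, bkhs, rng,
                                                         small_mixture):
        # feasible case: exact single-length measurements stay feasible
        from glycopoly.synthetic_data import GroundTruth, \
            synthesize_measurements

        truth = GroundTruth(kind="NI", n=5,
                            params={"gamma_S": rng.uniform(0.1, 0.5, 5)})
        ms_ok = synthesize_measurements(
            truth, bkhs.table.yields_, {d.enzyme: d.cap for d in bkhs.digests})
        w = lm.LengthDistribution(lengths=(5,), w=np.array([1.0]), mean=5.0)
        assert lm.equal_composition_feasibility(ms_ok, w) <= 1e-8
        assert pa.infeasibility(csys.assemble(ms_ok, build_space([5]))) <= 1e-8
        # infeasible case: mixture data forced onto one length fails both ways
        ms_bad, _, _ = small_mixture
        assert lm.equal_composition_feasibility(ms_bad, w) > 1e-6
        assert pa.infeasibility(csys.assemble(ms_bad, build_space([5]))) > 1e-6

    def test_matches_dense_oracle_at_toy_scale(self, small_mixture):
        ms, gamma_by_n, w = small_mixture
        wd = lm.LengthDistribution(
            lengths=tuple(sorted(w)), w=np.array([w[n] for n in sorted(w)]),
            mean=5.0)
        v = lm.equal_composition_feasibility(ms, wd)
        # dense reference over explicit strings
        seqs = [s for n in sorted(w) for s in enumerate_sequences(n)]
        rows, b = [], []
        for n in sorted(w):
            rows.append([1.0 if len(s) == n else 0.0 for s in seqs])
            b.append(w[n])
        rho_S = ms.table.rho[0]
        for n in sorted(w):
            rows.append([
                (s.count("S", 1) - rho_S * (n - 1)) if len(s) == n else 0.0
                for s in seqs])
            b.append(0.0)
        for d in ms.digests:
            qs = [brute_fragment_counts(s, ms.table.yields_[d.enzyme], d.cap)
                  for s in seqs]
            for l in range(1, d.cap + 1):
                rows.append([q[l - 1] - d.probs[l - 1] * Q for q, Q in qs])
                b.append(0.0)
        from oracles import brute_infeasibility

        v_ref = brute_infeasibility(np.array(rows), np.array(b))
        assert v == pytest.approx(v_ref, abs=1e-8)


class TestEndAlignedBounds:
    def test_reducing_end_better_estimated_after_re_alignment(self, bkhs):
        # scaled-down mixture of the measured chains: lengths 12..18,
        # mean 16, sigma 1.5
        w = lm.gaussian_length_distribution(16, 1.5, 12, 18)
        space = build_space(w.lengths)
        cs = csys.assemble(bkhs, space, w=w.w)
        lo_nre, hi_nre = pa.position_bounds(cs, space, 18, "S", "nre")
        assert lo_nre == pytest.approx(0.0, abs=1e-6)
        assert hi_nre == pytest.approx(1.0, abs=1e-6)
        lo_re, hi_re = pa.position_bounds(cs, space, 1, "S", "re")
        assert hi_re < 0.75  # the reducing end stays pinned down
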