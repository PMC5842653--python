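import numpy as np
import pytest
from scipy import stats

from methylising.ising import (
    RegionModel,
    block_marginal_likelihood,
    build_potentials,
    level_pmf,
    log_partition,
    sample_states,
    site_marginals,
    state_probability,
)

from conftest import enumerate_states


class TestBuildPotentials:
    def test_zero_theta_gives_fair_independent_sites(self):
        m = build_potentials((0, 0, 0, 0, 0), np.full(5, 0.02), 10 + 15 * np.arange(5))
        assert np.all(m.a == 0) and np.all(m.c == 0)

    def test_coupling_from_distance(self):
        m = build_potentials((0, 0, 0, 0, 1.0), np.full(2, 0.002), np.array([10, 12]))
        assert m.c[0] == pytest.approx(0.5)

    def test_field_from_density(self):
        m = build_potentials((0, 0, 0, 10.0, 0), np.full(3, 0.067), np.array([10, 25, 40]))
        assert m.a[1] == pytest.approx(0.67)

    def test_boundary_fields(self):
        m = build_potentials((1.0, 2.0, 3.0, 0, 0), np.zeros(4), np.arange(4) * 10 + 1)
        assert m.a.tolist() == [1.0, 2.0, 2.0, 3.0]

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            build_potentials((0, 0, 0, 0, 1), np.zeros(2), np.array([10, 10]))


class TestPartitionFunction:
    @pytest.mark.parametrize(
        "a,c,expected",
        [
            ([0.0], [], 2.0),
            ([0.0, 0.0], [0.0], 4.0),
            ([0.0, 0.0], [np.log(2)], 5.0),  # 2*e^ln2 + 2*e^-ln2
        ],
    )
    def test_small_exact(self, a, c, expected):
        assert np.exp(log_partition(RegionModel(a=a, c=c))) == pytest.approx(expected)

    def test_matches_enumeration(self, random_small_model):
        for _ in range(10):
            m = random_small_model()
            _, _, Z = enumerate_states(m)
            assert log_partition(m) == pytest.approx(np.log(Z), rel=1e-10)


class TestStateProbability:
    def test_frozen_examples(self):
        m = RegionModel(a=[0, 0], c=[np.log(2)])
        assert state_probability(m, [1, 1]) == pytest.approx(0.4)
        assert state_probability(m, [0, 1]) == pytest.approx(0.1)

    def test_normalization_and_enumeration(self, random_small_model):
        m = random_small_model()
        states, probs, _ = enumerate_states(m)
        computed = [state_probability(m, np.array(x)) for x in states]
        assert np.allclose(computed, probs, rtol=1e-10)
        assert sum(computed) == pytest.approx(1.0, abs=1e-10)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            state_probability(RegionModel(a=[0.0], c=[]), [2])


class TestSiteMarginals:
    def test_zero_field_symmetry(self, rng):
        m = RegionModel(a=np.zeros(6), c=rng.normal(0, 2, 5))
        assert np.allclose(site_marginals(m), 0.5, atol=1e-12)

    def test_saturation(self):
        m = RegionModel(a=np.full(4, 20.0), c=np.full(3, 1.0))
        assert np.all(site_marginals(m) > 0.999999)

    def test_matches_enumeration(self, random_small_model):
        for _ in range(10):
            m = random_small_model()
            states, probs, _ = enumerate_states(m)
            ref = np.zeros(m.n_sites)
            for x, p in zip(states, probs):
                ref += np.array(x) * p
            assert np.allclose(site_marginals(m), ref, atol=1e-10)

    def test_spin_flip_symmetry(self, random_small_model):
        m = random_small_model()
        flipped = RegionModel(a=-m.a, c=m.c)
        assert np.allclose(site_marginals(flipped), 1 - site_marginals(m), atol=1e-12)

    def test_mode_behavior(self, rng):
        # a<0, c>=0 -> all-zero state is the argmax; a>0 -> all-one
        for sign in (-1, 1):
            a = sign * rng.uniform(0.2, 2, 5)
            m = RegionModel(a=a, c=rng.uniform(0, 1.5, 4))
            states, probs, _ = enumerate_states(m)
            assert states[int(np.argmax(probs))] == tuple([max(sign, 0)] * 5)


class TestBlockMarginal:
    def test_single_site_symmetry(self):
        m = RegionModel(a=[0, 0], c=[np.log(2)])
        assert block_marginal_likelihood(m, {0: 1}) == pytest.approx(0.5)

    def test_full_observation(self):
        m = RegionModel(a=[0, 0], c=[np.log(2)])
        assert block_marginal_likelihood(m, {0: 1, 1: 1}) == pytest.approx(0.4)

    def test_noncontiguous_product_under_independence(self):
        m = RegionModel(a=np.zeros(3), c=np.zeros(2))
        assert block_marginal_likelihood(m, {0: 1, 2: 0}) == pytest.approx(0.25)

    def test_empty_observation(self):
        m = RegionModel(a=np.zeros(3), c=np.zeros(2))
        assert block_marginal_likelihood(m, {}) == 1.0

    def test_contiguous_matches_enumeration(self, random_small_model):
        for _ in range(10):
            m = random_small_model()
            R = m.n_sites
            s, e = 1, min(R, 4)
            obs = {i: int(i % 2) for i in range(s, e)}
            states, probs, _ = enumerate_states(m)
            ref = sum(
                p
                for x, p in zip(states, probs)
                if all(x[i] == v for i, v in obs.items())
            )
            assert block_marginal_likelihood(m, obs) == pytest.approx(ref, rel=1e-10)

    def test_completion_sums_to_one(self, random_small_model):
        # summing the marginal over all values of a fixed observed set is 1
        m = random_small_model(R=5)
        total = 0.0
        for v1 in (0, 1):
            for v2 in (0, 1):
                total += block_marginal_likelihood(m, {1: v1, 2: v2})
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLevelPMF:
    @pytest.mark.parametrize(
        "c,expected",
        [(0.0, (0.25, 0.5, 0.25)), (np.log(2), (0.4, 0.2, 0.4))],
    )
    def test_two_site_exact(self, c, expected):
        m = RegionModel(a=[0, 0], c=[c])
        assert level_pmf(m, 0, 2) == pytest.approx(np.array(expected), abs=1e-12)

    def test_saturated(self):
        m = RegionModel(a=np.full(5, 20.0), c=np.zeros(4))
        assert level_pmf(m, 0, 5)[-1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration_with_flanks(self, random_small_model):
        for _ in range(10):
            m = random_small_model(R=7)
            lo, hi = 2, 6
            states, probs, _ = enumerate_states(m)
            ref = np.zeros(hi - lo + 1)
            for x, p in zip(states, probs):
                ref[sum(x[lo:hi])] += p
            assert np.allclose(level_pmf(m, lo, hi), ref, atol=1e-10)

    def test_factorizes_when_uncoupled(self, rng):
        a = rng.normal(0, 1, 6)
        m = RegionModel(a=a, c=np.zeros(5))
        p1 = 1 / (1 + np.exp(-2 * a))
        # independent Bernoulli sum: Poisson-binomial PMF via polynomial product
        poly = np.array([1.0])
        for p in p1:
            poly = np.convolve(poly, [1 - p, p])
        assert np.allclose(level_pmf(m, 0, 6), poly, atol=1e-10)


class TestSampling:
    def test_fair_frequency(self):
        m = RegionModel(a=np.zeros(3), c=np.zeros(2))
        x = sample_states(m, 100_000, seed=7)
        assert np.allclose(x.mean(axis=0), 0.5, atol=0.005)

    def test_joint_matches_exact_distribution(self, random_small_model):
        m = random_small_model(R=3)
        states, probs, _ = enumerate_states(m)
        x = sample_states(m, 100_000, seed=11)
        codes = x @ np.array([4, 2, 1])
        counts = np.bincount(codes, minlength=8)
        expected = probs[[states.index(tuple(int(b) for b in f"{k:03b}")) for k in range(8)]]
        chi2 = stats.chisquare(counts, 100_000 * expected)
        assert chi2.pvalue > 0.001

    def test_strong_coupling_bistability(self):
        m = RegionModel(a=np.zeros(6), c=np.full(5, 5.0))
        x = sample_states(m, 5000, seed=3)
        sums = x.sum(axis=1)
        assert np.mean((sums == 0) | (sums == 6)) > 0.99

    def test_deterministic_given_seed(self):
        m = RegionModel(a=[0.3, -0.2], c=[0.5])
        assert np.array_equal(sample_states(m, 50, seed=5), sample_states(m, 50, seed=5))


def test_identifiability_distinct_parameters_distinct_distributions(rng):
    # distinct potentials produce a different probability for some state
    for _ in range(20):
        R = int(rng.integers(2, 6))
        m1 = RegionModel(a=rng.normal(0, 1, R), c=rng.normal(0, 1, R - 1))
        m2 = RegionModel(a=m1.a + rng.normal(0, 0.3, R), c=m1.c)
        states, p1, _ = enumerate_states(m1)
        _, p2, _ = enumerate_states(m2)
        assert np.max(np.abs(p1 - p2)) > 1e-12
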