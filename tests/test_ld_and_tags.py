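import numpy as np
import pytest

from trioassoc.ld_and_tags import em_haplotype_freqs, pairwise_ld, select_tag_snps
from trioassoc.synthetic_cohort import latent_model_r2, simulate_haplotype_pool

from helpers import phased_haplotype_freqs


def pool_genotypes(pool, n, seed):
    rng = np.random.default_rng(seed)
    i = rng.integers(pool.n_haplotypes, size=n)
    j = rng.integers(pool.n_haplotypes, size=n)
    return pool.haplotypes[i], pool.haplotypes[j]


class TestEM:
    def test_no_double_heterozygotes_resolves_by_counting_in_one_pass(self):
        ga = np.array([0, 0, 1, 2, 2, 1])
        gb = np.array([0, 0, 0, 2, 2, 2])  # never het at both markers
        res = em_haplotype_freqs(ga, gb)
        # haplotypes countable directly: each individual contributes two
        expected = np.array([5, 1, 1, 5]) / 12  # mm, mM, Mm, MM
        assert np.allclose(res.freqs, expected, atol=1e-9)
        assert res.n_iter <= 2

    def test_identical_genotype_vectors_put_mass_on_coupled_haplotypes(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        res = em_haplotype_freqs(g, g)
        f11, f10, f01, f00 = res.freqs
        assert f10 == pytest.approx(0.0, abs=1e-8)
        assert f01 == pytest.approx(0.0, abs=1e-8)
        assert f11 + f00 == pytest.approx(1.0)

    def test_em_matches_true_phase_counts_at_large_n(self):
        pool = simulate_haplotype_pool([(0.4, 0), (0.35, 0)], 100_000, 0.7, seed=51)
        h1, h2 = pool_genotypes(pool, 10_000, seed=52)
        res = em_haplotype_freqs((h1 + h2)[:, 0], (h1 + h2)[:, 1])
        truth = phased_haplotype_freqs(h1, h2, 0, 1)
        assert np.abs(res.freqs - truth).max() < 0.01

    def test_loglikelihood_never_decreases(self, rng):
        for _ in range(20):
            ga = rng.integers(0, 3, size=60)
            gb = rng.integers(0, 3, size=60)
            trace = em_haplotype_freqs(ga, gb).loglik_trace
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_monomorphic_marker_flagged(self):
        res = em_haplotype_freqs(np.zeros(10, dtype=int), np.array([0, 1, 2] * 3 + [1]))
        assert res.flagged_monomorphic

    def test_too_few_complete_pairs_rejected(self):
        with pytest.raises(ValueError):
            em_haplotype_freqs(np.array([1, -1]), np.array([-1, 1]))


class TestPairwiseLD:
    def test_independent_markers_have_near_zero_r2(self):
        pool = simulate_haplotype_pool([(0.4, 0), (0.4, 1)], 100_000, 0.9, seed=53)
        h1, h2 = pool_genotypes(pool, 20_000, seed=54)
        g = h1 + h2
        assert pairwise_ld(g[:, 0], g[:, 1]).r2 < 0.002

    def test_duplicated_marker_is_perfect_ld(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0, 1, 2])
        res = pairwise_ld(g, g)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.dprime == pytest.approx(1.0, abs=1e-9)

    def test_r2_matches_latent_model_oracle_for_adjacent_pair(self):
        pool = simulate_haplotype_pool([(0.4, 0), (0.4, 0)], 200_000, 0.95, seed=55)
        h1, h2 = pool_genotypes(pool, 50_000, seed=56)
        g = h1 + h2
        res = pairwise_ld(g[:, 0], g[:, 1])
        assert res.r2 == pytest.approx(latent_model_r2(0.4, 0.4, 0.95), abs=0.02)

    def test_invariant_under_allele_label_swap(self, rng):
        ga = rng.integers(0, 3, size=300)
        gb = rng.integers(0, 3, size=300)
        base = pairwise_ld(ga, gb)
        flipped = pairwise_ld(2 - ga, gb)
        assert flipped.r2 == pytest.approx(base.r2, abs=1e-9)
        assert flipped.dprime == pytest.approx(base.dprime, abs=1e-9)

    def test_d_consistency_identity(self, rng):
        ga = rng.integers(0, 3, size=400)
        gb = rng.integers(0, 3, size=400)
        res = pairwise_ld(ga, gb)
        f11, f10, f01, f00 = res.freqs
        pa, pb = f11 + f10, f11 + f01
        d = f11 - pa * pb
        assert res.r2 * pa * (1 - pa) * pb * (1 - pb) == pytest.approx(d * d, abs=1e-12)


class TestTagSelection:
    def test_complete_ld_collapses_to_one_bin(self):
        r2 = np.ones((5, 5))
        bins = select_tag_snps(r2, list(range(5)))
        assert len(bins.bins) == 1
        assert len(bins.bins[0].members) == 5

    def test_no_ld_makes_every_marker_its_own_tag(self):
        bins = select_tag_snps(np.eye(5), list(range(5)))
        assert len(bins.bins) == 5
        assert sorted(bins.tags) == ["0", "1", "2", "3", "4"]

    def test_planted_three_block_structure_is_recovered(self):
        within, between = 0.9, 0.1
        blocks = [0, 0, 0, 1, 1, 2, 2, 2]
        k = len(blocks)
        r2 = np.full((k, k), between)
        for i in range(k):
            for j in range(k):
                if blocks[i] == blocks[j]:
                    r2[i, j] = within
        np.fill_diagonal(r2, 1.0)
        bins = select_tag_snps(r2, list(range(k)))
        recovered = sorted(tuple(sorted(int(m) for m in b.members)) for b in bins.bins)
        assert recovered == [(0, 1, 2), (3, 4), (5, 6, 7)]

    def test_every_member_exceeds_threshold_with_its_tag(self, rng):
        k = 10
        a = rng.random((k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        bins = select_tag_snps(r2, list(range(k)), threshold=0.6)
        names = [str(i) for i in range(k)]
        for b in bins.bins:
            t = names.index(b.tag)
            for m in b.members:
                if m != b.tag:
                    assert r2[t, names.index(m)] > 0.6
        assert sorted(m for b in bins.bins for m in b.members) == sorted(names)

    def test_deterministic_for_fixed_matrix(self, rng):
        a = rng.random((8, 8))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        assert select_tag_snps(r2, list(range(8))) == select_tag_snps(r2, list(range(8)))

    def test_non_symmetric_matrix_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            select_tag_snps(bad, [1, 2, 3])
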