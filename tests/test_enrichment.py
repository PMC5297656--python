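from math import comb

import numpy as np
import pytest

from lncterplay.enrichment import enrich, hypergeom_p, permutation_p, significant_sets
from lncterplay.types import GeneSetCollection, ValidationError


def urn_tail(k, K, n, N):
    """Exact P(X >= k) by direct combinatorial enumeration."""
    return sum(
        comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
    ) / comb(N, n)


class TestHypergeomP:
    def test_zero_overlap_is_one(self):
        assert hypergeom_p(0, 5, 5, 20) == 1.0

    def test_full_overlap_small_urn(self):
        assert hypergeom_p(5, 5, 5, 10) == pytest.approx(1 / comb(10, 5))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_combinatorial_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 60))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeom_p(k, K, n, N) == pytest.approx(
            urn_tail(k, K, n, N), rel=1e-12
        )

    def test_non_increasing_in_k(self):
        ps = [hypergeom_p(k, 10, 15, 50) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValidationError):
            hypergeom_p(6, 5, 5, 10)


class TestPermutationP:
    UNIVERSE = {f"g{i}" for i in range(40)}

    def test_geneset_equal_universe_gives_one(self):
        query = {f"g{i}" for i in range(10)}
        p = permutation_p(query, set(self.UNIVERSE), self.UNIVERSE,
                          n_perm=200, seed=0)
        assert p == 1.0

    def test_add_one_lower_bound(self):
        query = {f"g{i}" for i in range(8)}
        gene_set = {f"g{i}" for i in range(8)}
        p = permutation_p(query, gene_set, self.UNIVERSE, n_perm=500, seed=1)
        assert p >= 1 / 501

    def test_agrees_with_hypergeometric_null(self):
        # the permutation null IS the urn model; check within 3 SE
        rng = np.random.default_rng(7)
        for _ in range(5):
            N = 50
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(5, 25))
            n = int(rng.integers(5, 25))
            gene_set = set(rng.choice(sorted(universe), K, replace=False))
            query = set(rng.choice(sorted(universe), n, replace=False))
            k = len(query & gene_set)
            p_h = hypergeom_p(k, K, n, N)
            n_perm = 20_000
            p_p = permutation_p(query, gene_set, universe, n_perm=n_perm, seed=3)
            se = np.sqrt(p_h * (1 - p_h) / n_perm)
            assert abs(p_p - p_h) <= 3 * se + 2 / n_perm

    def test_query_larger_than_universe_error(self):
        with pytest.raises(ValidationError):
            permutation_p({"a", "b"}, {"a"}, {"a"}, n_perm=100, seed=0)


class TestEnrich:
    def make_collection(self, rng, universe, n_sets=10, size=8):
        ids = sorted(universe)
        sets = {
            f"S{k:02d}": {str(g) for g in rng.choice(ids, size, replace=False)}
            for k in range(n_sets)
        }
        return GeneSetCollection(sets=sets, universe=set(universe))

    def test_planted_set_is_significant(self, small_dataset):
        ds = small_dataset
        truth = ds.truth
        de = truth.de_up | truth.de_down
        query = {g for _, g in truth.cis_pairs | truth.trans_pairs if g in de}
        universe = {f.feature_id for f in ds.annotation.genes}
        results = enrich(query, ds.genesets, universe, n_perm=500, seed=2)
        sig = significant_sets(results, alpha=0.05)
        assert truth.enriched_set_ids <= sig

    def test_duplicate_query_genes_deduplicated(self):
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(50)}
        gs = self.make_collection(rng, universe)
        res_a = enrich(["g0", "g1", "g1", "g2"], gs, universe, seed=5)
        res_b = enrich(["g0", "g1", "g2"], gs, universe, seed=5)
        assert [(r.set_id, r.overlap, r.query_size) for r in res_a] == [
            (r.set_id, r.overlap, r.query_size) for r in res_b
        ]

    def test_disjoint_query_universe_error(self):
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(50)}
        gs = self.make_collection(rng, universe)
        with pytest.raises(ValidationError):
            enrich({"absent"}, gs, universe)

    def test_null_queries_not_inflated(self):
        # uniform random queries: the significant fraction stays near alpha
        rng = np.random.default_rng(42)
        universe = {f"g{i}" for i in range(60)}
        gs = self.make_collection(rng, universe, n_sets=5, size=10)
        n_sig = 0
        n_tests = 0
        for s in range(40):
            q_rng = np.random.default_rng(1000 + s)
            query = {str(g) for g in q_rng.choice(sorted(universe), 12,
                                                  replace=False)}
            results = enrich(query, gs, universe, n_perm=200, seed=s)
            n_sig += sum(1 for r in results if r.p_permutation < 0.05)
            n_tests += len(results)
        rate = n_sig / n_tests
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)

    def test_q_values_preserve_bh_order(self):
        rng = np.random.default_rng(3)
        universe = {f"g{i}" for i in range(50)}
        gs = self.make_collection(rng, universe)
        results = enrich({f"g{i}" for i in range(10)}, gs, universe, seed=0)
        ps = [r.p_hypergeom for r in results]
        qs = [r.q_value for r in results]
        assert all(q >= p for p, q in zip(ps, qs))
        assert all(a <= b for a, b in zip(qs, qs[1:]))  # sorted by p
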