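import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from triagene import (EnrichmentResult, GeneSetCollection, classical_mds,
                      hypergeom_enrich, jaccard_distance_matrix, k_medoids,
                      mds_cluster, mds_stress)


def exact_upper_tail(N, K, n, k):
    """Exact-rational hypergeometric upper tail P(X >= k)."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j),
                          math.comb(N, n))
    return float(total)


def result(name, genes, p):
    return EnrichmentResult(name, sorted(genes), len(genes), len(genes),
                            0, 0, p)


class TestHypergeomEnrich:
    def test_full_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"S": universe[:5]})
        res = hypergeom_enrich(universe[:5], coll, universe)
        assert res[0].p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_exact_enumeration_small(self):
        # sweep every configuration with a universe of up to 12 genes
        from scipy import stats

        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = exact_upper_tail(N, K, n, k)
                        got = float(stats.hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection({"S": universe[20:30]})
        res = hypergeom_enrich(universe[:5], coll, universe)
        assert res[0].k == 0
        assert res[0].p == 1.0

    def test_size_filter_excludes_small_sets(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection({"tiny": universe[:4], "ok": universe[:6]})
        res = hypergeom_enrich(universe[:5], coll, universe)
        assert [r.name for r in res] == ["ok"]

    def test_query_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"S": universe[:10]})
        with pytest.warns(UserWarning):
            res = hypergeom_enrich(universe[:5] + ["alien"], coll, universe)
        assert res[0].n == 5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["a"], GeneSetCollection({}), [])

    def test_bh_fdr_monotone_and_bounded(self, rng):
        universe = [f"g{i}" for i in range(100)]
        sets = {f"S{i}": list(rng.choice(universe, size=20, replace=False))
                for i in range(30)}
        res = hypergeom_enrich(list(universe[:15]),
                               GeneSetCollection(sets), universe)
        fdrs = [r.fdr for r in res]  # results sorted by p
        assert all(f <= 1 + 1e-12 for f in fdrs)
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestJaccard:
    def test_identical_disjoint_partial(self):
        rs = [result("A", {"a", "b", "c"}, 0.01),
              result("B", {"a", "b", "c"}, 0.02),
              result("C", {"x", "y"}, 0.03),
              result("D", {"b", "c", "d"}, 0.04)]
        d = jaccard_distance_matrix(rs)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0
        assert d[0, 3] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            jaccard_distance_matrix([result("A", {"a"}, 0.5)])


class TestClassicalMds:
    def test_two_points_exact(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        coords = classical_mds(d)
        sep = np.linalg.norm(coords[0] - coords[1])
        assert sep == pytest.approx(0.7, abs=1e-12)

    def test_zero_stress_on_planar_configuration(self, rng):
        pts = rng.uniform(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = classical_mds(d)
        assert mds_stress(d, coords) <= 1e-10


class TestKMedoids:
    def brute_force_two_partition(self, d):
        m = d.shape[0]
        best, best_cost = None, np.inf
        for mask in range(1, 2 ** (m - 1)):
            g1 = [i for i in range(m) if (mask >> i) & 1]
            g2 = [i for i in range(m) if not (mask >> i) & 1]
            cost = 0.0
            for grp in (g1, g2):
                cost += min(sum(d[i, c] for i in grp) for c in grp)
            if cost < best_cost:
                best_cost, best = cost, frozenset(map(frozenset, (g1, g2)))
        return best

    def test_recovers_two_groups_exactly(self, rng):
        # tight within-group, far between-group Jaccard-like distances
        m = 7
        groups = [0, 0, 0, 1, 1, 1, 1]
        d = np.zeros((m, m))
        for i, j in itertools.combinations(range(m), 2):
            base = 0.1 if groups[i] == groups[j] else 0.95
            d[i, j] = d[j, i] = base + rng.uniform(0, 0.05)
        labels, _ = k_medoids(d, 2, seed=0)
        found = frozenset(frozenset(np.flatnonzero(labels == c)) for c in (0, 1))
        assert found == self.brute_force_two_partition(d)

    def test_k_equals_n_singletons(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        labels, medoids = k_medoids(d, 3, seed=1)
        assert sorted(labels) == [0, 1, 2]

    def test_invalid_k_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            k_medoids(d, 0)
        with pytest.raises(ValueError):
            k_medoids(d, 4)


class TestMdsCluster:
    def test_representatives_have_lowest_p(self, rng):
        m = 6
        pts = rng.uniform(size=(m, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        pv = rng.uniform(size=m)
        emb = mds_cluster(d, pv, k=2, seed=3)
        for c, grp in emb.groupby("CLUSTER"):
            rep = grp.loc[grp["REPRESENTATIVE"]]
            assert len(rep) == 1
            assert rep["P"].iloc[0] == grp["P"].min()

    def test_singleton_clusters_all_representatives(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        emb = mds_cluster(d, np.array([0.1, 0.2, 0.3]), k=3, seed=0)
        assert emb["REPRESENTATIVE"].all()
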