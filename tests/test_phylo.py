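import itertools

import numpy as np
import pytest
from scipy import stats

from ithkit import phylo
from ithkit.ith import PairwiseDistances


def _pd(values, ids=None, metric="scna_proportion"):
    values = np.asarray(values, float)
    if ids is None:
        ids = [f"s{i}" for i in range(values.shape[0])]
    return PairwiseDistances(list(ids), values, metric)


def _random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns (adjacency,
    lengths, leaf labels) and the implied additive distance matrix."""
    leaves = [f"s{i}" for i in range(n_leaves)]
    # start from a 3-leaf star, insert remaining leaves on random edges
    adjacency = {0: set(leaves[:3])}
    for leaf in leaves[:3]:
        adjacency[leaf] = {0}
    lengths = {frozenset((0, leaf)): rng.uniform(0.1, 1.0) for leaf in leaves[:3]}
    next_internal = 1
    for leaf in leaves[3:]:
        edges = [tuple(e) for e in lengths]
        a, b = edges[rng.integers(len(edges))]
        w = lengths.pop(frozenset((a, b)))
        node = next_internal
        next_internal += 1
        adjacency[a].discard(b)
        adjacency[b].discard(a)
        adjacency[node] = {a, b, leaf}
        adjacency[a].add(node)
        adjacency[b].add(node)
        adjacency[leaf] = {node}
        split = rng.uniform(0.2, 0.8)
        lengths[frozenset((a, node))] = w * split
        lengths[frozenset((b, node))] = w * (1 - split)
        lengths[frozenset((leaf, node))] = rng.uniform(0.1, 1.0)
    # path-sum distances
    d = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        path = phylo._path(adjacency, leaves[i], leaves[j])
        dist = sum(
            lengths[frozenset((a, b))] for a, b in zip(path[:-1], path[1:])
        )
        d[i, j] = d[j, i] = dist
    return phylo.PhyloTree(leaves, adjacency, lengths), d


class TestCombineDistances:
    def test_forced_arithmetic(self):
        d1 = _pd([[0, 2], [2, 0]])
        d2 = _pd([[0, 4], [4, 0]], metric="methylation_euclidean")
        out = phylo.combine_distances(d1, d2)
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_proportional_matrices_coincide_after_normalization(self, rng):
        base = _pd_random(rng, 5)
        d1 = _pd(base)
        d2 = _pd(2.0 * base, metric="methylation_euclidean")
        out = phylo.combine_distances(d1, d2)
        assert np.allclose(out.values, base / base.max())

    def test_matches_direct_formula_on_random_pair(self, rng):
        a, b = _pd_random(rng, 6), _pd_random(rng, 6)
        out = phylo.combine_distances(_pd(a), _pd(b, metric="m"))
        expect = 0.5 * (a / a.max() + b / b.max())
        assert np.abs(out.values - expect).max() < 1e-12

    def test_scna_only_fallback(self, rng):
        a = _pd_random(rng, 4)
        out = phylo.combine_distances(_pd(a))
        assert np.allclose(out.values, a / a.max())

    def test_missing_methylation_samples_use_scna_term(self, rng):
        a = _pd_random(rng, 4)
        d1 = _pd(a, ids=list("wxyz"))
        b = _pd_random(rng, 2)
        d2 = _pd(b, ids=["w", "x"], metric="m")
        out = phylo.combine_distances(d1, d2)
        assert out.values[0, 1] == pytest.approx(
            0.5 * (a[0, 1] / a.max() + b[0, 1] / b.max())
        )
        assert out.values[2, 3] == pytest.approx(a[2, 3] / a.max())

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.combine_distances(_pd(np.zeros((3, 3))))


def _pd_random(rng, k):
    iu = np.triu_indices(k, 1)
    d = np.zeros((k, k))
    d[iu] = rng.uniform(0.1, 1.0, len(iu[0]))
    return d + d.T


class TestBuildTree:
    def test_three_leaf_closed_form(self):
        # d12=0.3, d13=0.5, d23=0.6 -> x1=0.1, x2=0.2, x3=0.4
        d = _pd([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = phylo.build_tree(d)
        internal = [n for n in tree.adjacency if not isinstance(n, str)]
        assert len(internal) == 1
        lengths = {
            leaf: tree.branch_lengths[frozenset((internal[0], leaf))]
            for leaf in tree.leaves
        }
        assert lengths["s0"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["s1"] == pytest.approx(0.2, abs=1e-9)
        assert lengths["s2"] == pytest.approx(0.4, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_six_leaf_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        true_tree, d = _random_additive_tree(rng, 6)
        est = phylo.build_tree(_pd(d))
        raw, norm = phylo.tree_distance(true_tree, est)
        assert raw == 0
        # additive distances also reproduced by the OLS branch lengths
        for i, j in itertools.combinations(range(6), 2):
            path = phylo._path(est.adjacency, f"s{i}", f"s{j}")
            dist = sum(
                est.branch_lengths[frozenset((a, b))]
                for a, b in zip(path[:-1], path[1:])
            )
            assert dist == pytest.approx(d[i, j], abs=1e-6)

    def test_star_matrix_gives_zero_internal_branches(self):
        k = 6
        d = np.full((k, k), 0.8)
        np.fill_diagonal(d, 0.0)
        tree = phylo.build_tree(_pd(d))
        for e, ln in tree.branch_lengths.items():
            if all(not isinstance(x, str) for x in e):  # internal edge
                assert ln == pytest.approx(0.0, abs=1e-9)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            phylo.build_tree(_pd([[0, 1], [1, 0]]))

    def test_newick_roundtrip_via_skbio(self, rng):
        _, d = _random_additive_tree(rng, 5)
        tree = phylo.build_tree(_pd(d))
        sk = tree.to_skbio()
        assert {t.name for t in sk.tips()} == set(tree.leaves)


class TestCongruence:
    def test_monotone_transform_rho_one(self, rng):
        a = _pd_random(rng, 5)
        d1 = _pd(a)
        d2 = _pd(a**2, metric="m")  # monotone on positives
        out = phylo.congruence([d1], [d2], n_perm=99)
        assert out["rho"] == pytest.approx(1.0)

    def test_negative_monotone_transform_rho_minus_one(self, rng):
        a = _pd_random(rng, 5)
        neg = 2.0 - a
        np.fill_diagonal(neg, 0.0)
        out = phylo.congruence([_pd(a)], [_pd(neg, metric="m")], n_perm=99)
        assert out["rho"] == pytest.approx(-1.0)

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        """4 samples: permutation p equals the exhaustive p over all 4!
        relabelings."""
        a, b = _pd_random(rng, 4), _pd_random(rng, 4)
        d1, d2 = _pd(a), _pd(b, metric="m")
        out = phylo.congruence([d1], [d2], n_perm=0, exhaustive=True)
        iu = np.triu_indices(4, 1)
        obs = stats.spearmanr(a[iu], b[iu]).statistic
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            bp = b[np.ix_(p, p)]
            if abs(stats.spearmanr(a[iu], bp[iu]).statistic) >= abs(obs) - 1e-12:
                hits += 1
        assert out["p"] == pytest.approx(hits / len(perms))

    def test_too_few_pairs_rejected(self, rng):
        d1 = _pd(_pd_random(rng, 2))
        d2 = _pd(_pd_random(rng, 2), metric="m")
        with pytest.raises(ValueError):
            phylo.congruence([d1], [d2], n_perm=9)


class TestTreeDistance:
    def test_identical_trees_zero(self, rng):
        tree, _ = _random_additive_tree(rng, 6)
        assert phylo.tree_distance(tree, tree) == (0, 0.0)

    def test_two_distinct_four_leaf_topologies_normalized_one(self):
        # ((s0,s1),(s2,s3)) vs ((s0,s2),(s1,s3))
        def quartet(pairing):
            (a, b), (c, d) = pairing
            adjacency = {
                0: {a, b, 1}, 1: {c, d, 0},
                a: {0}, b: {0}, c: {1}, d: {1},
            }
            lengths = {frozenset(e): 1.0 for e in
                       [(0, a), (0, b), (1, c), (1, d), (0, 1)]}
            return phylo.PhyloTree([a, b, c, d], adjacency, lengths)
        t1 = quartet((("s0", "s1"), ("s2", "s3")))
        t2 = quartet((("s0", "s2"), ("s1", "s3")))
        raw, norm = phylo.tree_distance(t1, t2)
        assert (raw, norm) == (2, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_bipartition_comparison(self, seed):
        rng = np.random.default_rng(seed)
        t1, _ = _random_additive_tree(rng, 8)
        t2, _ = _random_additive_tree(rng, 8)

        def brute_bipartitions(tree):
            parts = set()
            leafset = frozenset(tree.leaves)
            for a in tree.adjacency:
                for b in tree.adjacency[a]:
                    side = frozenset(tree._leafset_beyond(a, b))
                    if 1 < len(side) < len(leafset) - 1:
                        parts.add(frozenset({side, leafset - side}))
            return parts

        raw, _ = phylo.tree_distance(t1, t2)
        b1, b2 = brute_bipartitions(t1), brute_bipartitions(t2)
        assert raw == len(b1 ^ b2)

    def test_matches_dendropy_oracle(self, rng):
        dendropy = pytest.importorskip("dendropy")
        t1, _ = _random_additive_tree(rng, 7)
        t2, _ = _random_additive_tree(rng, 7)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                               taxon_namespace=tns)
        expect = dendropy.calculate.treecompare.symmetric_difference(
            d1, d2, is_bipartitions_updated=False
        )
        assert phylo.tree_distance(t1, t2)[0] == expect

    def test_leaf_set_mismatch_rejected(self, rng):
        t1, _ = _random_additive_tree(rng, 5)
        t2, _ = _random_additive_tree(rng, 6)
        with pytest.raises(ValueError):
            phylo.tree_distance(t1, t2)
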