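"""Distances, neighbor joining, bootstrap and gene structure."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genefam import phylo_structure as ps
from genefam.seq_io import GeneModel


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths, its
    path-length distance matrix, and its internal bipartitions."""
    # grow by attaching leaves to random edges of a 3-leaf star
    adjacency: dict[int, dict[int, float]] = {}
    names = {i: f"t{i + 1}" for i in range(n_taxa)}

    def connect(u, v, w):
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    center = n_taxa
    next_internal = n_taxa + 1
    for leaf in range(3):
        connect(leaf, center, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adjacency for v in adjacency[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adjacency[u].pop(v)
        adjacency[v].pop(u)
        mid = next_internal
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * split)
        connect(v, mid, w * (1 - split))
        connect(leaf, mid, float(rng.uniform(0.1, 1.0)))

    tree = ps.PhyloTree(adjacency, names)
    # path-length distances by BFS from each leaf
    dist = pd.DataFrame(0.0, index=list(names.values()), columns=list(names.values()))
    for leaf in names:
        lengths = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nbr, w in adjacency[node].items():
                if nbr not in lengths:
                    lengths[nbr] = lengths[node] + w
                    stack.append(nbr)
        for other, name in names.items():
            dist.loc[names[leaf], name] = lengths[other]
    return tree, dist


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        d = ps.distance_matrix({"a": "MKVL", "b": "MKVL", "c": "MKAL"})
        assert d.loc["a", "b"] == 0.0

    def test_poisson_correction_value(self):
        # 1 mismatch over 10 shared columns: d = -ln(0.9)
        aln = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC", "c": "AAAAAAAAAA"}
        d = ps.distance_matrix(aln)
        assert d.loc["a", "b"] == pytest.approx(-math.log(0.9))

    def test_symmetric_zero_diagonal(self):
        aln = {"a": "MKVLAD", "b": "MKVEAD", "c": "QKVLAD", "d": "MKVLWD"}
        d = ps.distance_matrix(aln)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_gap_columns_excluded(self):
        d = ps.distance_matrix({"a": "MK-L", "b": "MKV-", "c": "MKVL"})
        assert d.loc["a", "b"] == 0.0  # only M, K shared

    def test_no_shared_columns(self):
        with pytest.raises(ValueError, match="share no aligned columns"):
            ps.distance_matrix({"a": "MK--", "b": "--VL", "c": "MKVL"})


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_tree_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            true_tree, dist = random_additive_tree(n_taxa, rng)
            est = ps.nj_tree(dist)
            assert est.internal_bipartitions() == true_tree.internal_bipartitions()
            # branch lengths: compare leaf-to-leaf path distances
            est_d = {}
            for a, b in itertools.combinations(est.leaves, 2):
                est_d[(a, b)] = None
            # additive recovery implies the NJ distances reproduce input
            for a, b in est_d:
                assert _path_length(est, a, b) == pytest.approx(dist.loc[a, b], abs=1e-9)

    def test_four_taxon_least_squares_check(self):
        """NJ picks the topology an exhaustive least-squares fit over all
        three unrooted quartet topologies prefers."""
        rng = np.random.default_rng(77)
        _, dist = random_additive_tree(4, rng)
        est = ps.nj_tree(dist)
        names = list(dist.index)
        best = None
        for split in [(0, 1), (0, 2), (0, 3)]:
            pair = {names[split[0]], names[split[1]]}
            rest = [n for n in names if n not in pair]
            # quartet (ab|cd) residual via the four-point condition
            a, b = sorted(pair)
            c, d = sorted(rest)
            resid = abs(
                (dist.loc[a, c] + dist.loc[b, d]) - (dist.loc[a, d] + dist.loc[b, c])
            )
            if best is None or resid < best[0]:
                best = (resid, frozenset(pair))
        (bip,) = est.internal_bipartitions()
        ref = min(names)
        expected = best[1] if ref not in best[1] else frozenset(set(names) - best[1])
        assert bip == expected

    def test_three_taxa_unique_topology(self):
        dist = pd.DataFrame(
            [[0, 2, 3], [2, 0, 3], [3, 3, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        tree = ps.nj_tree(dist)
        assert tree.internal_bipartitions() == set()
        assert sorted(tree.leaves) == ["a", "b", "c"]

    def test_ultrametric_tie_is_deterministic(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        dist = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        t1 = ps.nj_tree(dist)
        t2 = ps.nj_tree(dist)
        assert t1.to_newick(with_support=False) == t2.to_newick(with_support=False)

    def test_asymmetric_rejected(self):
        dist = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc")
        )
        with pytest.raises(ValueError, match="symmetric"):
            ps.nj_tree(dist)

    def test_agrees_with_skbio(self):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix

        rng = np.random.default_rng(13)
        true_tree, dist = random_additive_tree(6, rng)
        dist = (dist + dist.T) / 2.0  # remove float asymmetry from path sums
        ours = ps.nj_tree(dist)
        ref = skbio_tree.nj(DistanceMatrix(dist.values, list(dist.index)))
        ref_bips = set()
        leaves = set(dist.index)
        ref_leaf = min(leaves)
        for node in ref.non_tips():
            side = {t.name for t in node.tips()}
            if 2 <= len(side) <= len(leaves) - 2:
                ref_bips.add(
                    frozenset(side if ref_leaf not in side else leaves - side)
                )
        assert ours.internal_bipartitions() == ref_bips


def _path_length(tree: ps.PhyloTree, a: str, b: str) -> float:
    ids = {name: node for node, name in tree.leaf_names.items()}
    start, goal = ids[a], ids[b]
    lengths = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, w in tree.adjacency[node].items():
            if nbr not in lengths:
                lengths[nbr] = lengths[node] + w
                stack.append(nbr)
    return lengths[goal]


class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, family):
        t1 = ps.bootstrap(family.alignment, n=100, seed=5)
        t2 = ps.bootstrap(family.alignment, n=100, seed=5)
        assert t1.supports == t2.supports
        assert all(0 <= v <= 100 for v in t1.supports.values())

    def test_separated_clades_high_support(self, family):
        tree = ps.bootstrap(family.alignment, n=200, seed=5)
        truth = family.truth.classes
        leaves = set(tree.leaves)
        ref = min(leaves)
        for clade_no in (1, 3):
            side = {g for g, c in truth.items() if c == clade_no}
            key = frozenset(side if ref not in side else leaves - side)
            assert tree.supports.get(key, 0.0) >= 95.0


class TestAssignClasses:
    def test_planted_clades_recovered(self, family):
        tree = ps.nj_tree(ps.distance_matrix(family.alignment))
        classes = ps.assign_classes(tree, k=3)
        truth = family.truth.classes
        found = {frozenset(g for g in classes if classes[g] == c) for c in {1, 2, 3}}
        expected = {frozenset(g for g in truth if truth[g] == c) for c in {1, 2, 3}}
        assert found == expected
        # numbering by decreasing size: class 1 is the large clade
        sizes = {c: sum(1 for v in classes.values() if v == c) for c in {1, 2, 3}}
        assert sizes[1] >= sizes[2] >= sizes[3]

    def test_k_one_single_class(self, family):
        tree = ps.nj_tree(ps.distance_matrix(family.alignment))
        assert set(ps.assign_classes(tree, k=1).values()) == {1}

    def test_k_equals_leaf_count_singletons(self):
        rng = np.random.default_rng(2)
        _, dist = random_additive_tree(5, rng)
        tree = ps.nj_tree(dist)
        classes = ps.assign_classes(tree, k=5)
        assert sorted(classes.values()) == [1, 2, 3, 4, 5]

    def test_k_exceeding_leaves_rejected(self):
        rng = np.random.default_rng(2)
        _, dist = random_additive_tree(4, rng)
        with pytest.raises(ValueError):
            ps.assign_classes(ps.nj_tree(dist), k=9)

    def test_invariant_to_input_order(self, family):
        items = list(family.alignment.items())
        shuffled = dict(reversed(items))
        c1 = ps.assign_classes(ps.nj_tree(ps.distance_matrix(family.alignment)), 3)
        c2 = ps.assign_classes(ps.nj_tree(ps.distance_matrix(shuffled)), 3)
        p1 = {frozenset(g for g in c1 if c1[g] == c) for c in set(c1.values())}
        p2 = {frozenset(g for g in c2 if c2[g] == c) for c in set(c2.values())}
        assert p1 == p2


class TestGeneStructure:
    def test_counts(self):
        gm_single = GeneModel("g1", "chr1", "+", cds_intervals=[(1, 300)], exon_intervals=[(1, 300)])
        intervals = [(1 + 100 * i, 50 + 100 * i) for i in range(34)]
        gm_many = GeneModel("g2", "chr1", "+", cds_intervals=intervals, exon_intervals=intervals)
        stats = {s.gene_id: s for s in ps.exon_intron_stats([gm_single, gm_many])}
        assert stats["g1"].intron_count == 0
        assert stats["g2"].intron_count == 33
        assert stats["g1"].cds_length == 300

    def test_empty_input(self):
        assert ps.exon_intron_stats([]) == []

    def test_generator_spans_intron_range(self, family):
        stats = ps.exon_intron_stats(list(family.models.values()))
        counts = {s.intron_count for s in stats}
        assert min(counts) == 0
        assert max(counts) <= 33


def test_newick_output_parses(family, tmp_path):
    dendropy = pytest.importorskip("dendropy")
    tree = ps.bootstrap(family.alignment, n=50, seed=1)
    newick = tree.to_newick()
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(family.alignment)
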