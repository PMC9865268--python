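"""Distance-based family phylogeny and exon–intron structure statistics.

The tree is built by Saitou–Nei neighbor joining on Poisson-corrected
protein distances (d = −ln(1 − p) over shared non-gap columns), with
per-edge bootstrap support from column resampling.  Neighbor joining
exactly recovers additive trees; ties in the Q criterion are broken
deterministically by the smallest pair of cluster labels (each cluster
labelled by its lexicographically smallest leaf), so a fixed input
yields a fixed tree.

Family classes are obtained by cutting the k−1 longest internal edges;
the resulting connected leaf sets are numbered by size descending.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import GeneModel

__all__ = [
    "PhyloTree",
    "GeneStructureStat",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "assign_classes",
    "exon_intron_stats",
]


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency map with branch lengths, named leaves.

    ``supports`` maps canonical bipartitions (frozenset of the leaf side
    not containing the reference leaf) to percent bootstrap support.
    """

    adjacency: dict[int, dict[int, float]]
    leaf_names: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def _leaf_side(self, u: int, v: int) -> set[str]:
        """Leaves reachable from v without crossing the edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out: set[str] = set()
        while stack:
            node = stack.pop()
            if node in self.leaf_names:
                out.add(self.leaf_names[node])
            for nbr in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self.adjacency):
            for v, length in self.adjacency[u].items():
                if u < v:
                    out.append((u, v, length))
        return out

    def bipartition(self, u: int, v: int) -> frozenset:
        """Canonical bipartition key of an edge: the side without the
        lexicographically smallest leaf."""
        side = self._leaf_side(u, v)
        ref = min(self.leaves)
        if ref in side:
            side = set(self.leaves) - side
        return frozenset(side)

    def internal_edges(self) -> list[tuple[int, int, float]]:
        """Edges whose removal splits the leaves ≥2 / ≥2."""
        n = len(self.leaf_names)
        out = []
        for u, v, length in self.edges():
            size = len(self._leaf_side(u, v))
            if 2 <= size <= n - 2:
                out.append((u, v, length))
        return out

    def internal_bipartitions(self) -> set[frozenset]:
        return {self.bipartition(u, v) for u, v, _ in self.internal_edges()}

    def to_newick(self, with_support: bool = True) -> str:
        # root at the neighbor of the first leaf (or the leaf itself for n=2)
        first_leaf = min(self.leaf_names, key=lambda n: self.leaf_names[n])
        root = next(iter(self.adjacency[first_leaf]))

        def render(node: int, parent: int) -> str:
            if node in self.leaf_names:
                return self.leaf_names[node]
            parts = [
                render(child, node) + f":{self.adjacency[node][child]:.6f}"
                for child in sorted(self.adjacency[node])
                if child != parent
            ]
            label = ""
            if with_support and parent is not None:
                key = self.bipartition(parent, node)
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return "(" + ",".join(parts) + ")" + label

        if root in self.leaf_names:  # two-leaf tree
            other = first_leaf
            return f"({self.leaf_names[other]}:{self.adjacency[root][other]:.6f},{self.leaf_names[root]}:0.0);"
        return render(root, None) + ";"


@dataclass(frozen=True)
class GeneStructureStat:
    gene_id: str
    exon_count: int
    intron_count: int
    cds_length: int


def distance_matrix(alignment: Mapping[str, str]) -> pd.DataFrame:
    """Poisson-corrected pairwise distances over an aligned protein set.

    p is the mismatch proportion over columns where neither row has a
    gap; d = −ln(1 − p).  Raises on saturated pairs (p ≥ 1, impossible
    unless no shared columns) and on pairs sharing no columns.
    """
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    arr = np.array([list(alignment[n]) for n in names])
    nongap = arr != "-"
    d = pd.DataFrame(0.0, index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        shared = nongap[i] & nongap[j]
        n_shared = int(shared.sum())
        if n_shared == 0:
            raise ValueError(f"{names[i]} and {names[j]} share no aligned columns")
        p = float((arr[i][shared] != arr[j][shared]).sum()) / n_shared
        if p >= 1.0:
            raise ValueError(f"{names[i]} and {names[j]}: saturated distance (p = 1)")
        dist = -math.log(1.0 - p)
        d.iat[i, j] = d.iat[j, i] = dist
    return d


def nj_tree(dist: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Negative branch lengths are clamped to zero.  Q-ties are broken by
    the smallest (label, label) pair, labels being each cluster's
    smallest leaf name.
    """
    names = list(dist.index)
    if list(dist.columns) != names:
        raise ValueError("distance matrix index and columns differ")
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")
    if (mat < 0).any():
        raise ValueError("negative distances")
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = dict(enumerate(names))
    labels = {i: names[i] for i in range(n)}  # smallest leaf per cluster
    active = list(range(n))
    D = {(i, j): mat[i, j] for i in range(n) for j in range(n) if i != j}
    next_id = n

    def add_edge(u: int, v: int, length: float) -> None:
        length = max(0.0, length)
        adjacency.setdefault(u, {})[v] = length
        adjacency.setdefault(v, {})[u] = length

    while len(active) > 3 or (len(active) == 2 and n == 2):
        if len(active) == 2:
            i, j = active
            add_edge(i, j, D[(i, j)])
            return PhyloTree(adjacency, leaf_names)
        m = len(active)
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * D[(i, j)] - r[i] - r[j]
            tie = tuple(sorted((labels[i], labels[j])))
            cand = (q, tie, i, j)
            if best is None or cand < best:
                best = cand
        _, _, i, j = best
        u = next_id
        next_id += 1
        dij = D[(i, j)]
        bi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dij - bi
        add_edge(i, u, bi)
        add_edge(j, u, bj)
        labels[u] = min(labels[i], labels[j])
        active = [k for k in active if k not in (i, j)]
        for k in active:
            D[(u, k)] = D[(k, u)] = max(0.0, 0.5 * (D[(i, k)] + D[(j, k)] - dij))
        active.append(u)

    if len(active) == 3:
        i, j, k = active
        u = next_id
        add_edge(i, u, 0.5 * (D[(i, j)] + D[(i, k)] - D[(j, k)]))
        add_edge(j, u, 0.5 * (D[(i, j)] + D[(j, k)] - D[(i, k)]))
        add_edge(k, u, 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)]))
    return PhyloTree(adjacency, leaf_names)


def bootstrap(alignment: Mapping[str, str], n: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree with per-internal-edge bootstrap support.

    Columns are resampled with replacement ``n`` times; support of an
    edge is the percentage of replicate trees containing the same leaf
    bipartition.  Fully deterministic for a fixed seed.
    """
    names = list(alignment)
    arr = np.array([list(alignment[name]) for name in names])
    n_cols = arr.shape[1]
    if n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")
    base = nj_tree(distance_matrix(alignment))
    targets = base.internal_bipartitions()
    counts = {key: 0 for key in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = arr[:, cols]
        replicate_aln = {name: "".join(sub[i]) for i, name in enumerate(names)}
        try:
            rep_tree = nj_tree(distance_matrix(replicate_aln))
        except ValueError:  # saturated replicate; counts as non-support
            continue
        rep_bips = rep_tree.internal_bipartitions()
        for key in targets & rep_bips:
            counts[key] += 1
    base.supports = {key: 100.0 * c / n for key, c in counts.items()}
    return base


def assign_classes(tree: PhyloTree, k: int = 3) -> dict[str, int]:
    """Cut the k−1 longest internal edges; components become classes.

    Classes are numbered 1..k by decreasing size (ties by smallest leaf
    name).  ``k`` may not exceed the number of leaves; when there are
    fewer than k−1 internal edges the cut falls back to all edges sorted
    by length (covers k = leaf count, i.e. singleton classes).
    """
    leaves = tree.leaves
    if k < 1 or k > len(leaves):
        raise ValueError(f"k={k} outside [1, {len(leaves)}]")
    if k == 1:
        return {leaf: 1 for leaf in leaves}
    if k == len(leaves):
        return {leaf: i for i, leaf in enumerate(sorted(leaves), start=1)}
    internal = tree.internal_edges()
    pool = internal if len(internal) >= k - 1 else tree.edges()
    pool = sorted(
        pool, key=lambda e: (-e[2], sorted(tree._leaf_side(e[0], e[1]))[0])
    )
    cut = {(u, v) for u, v, _ in pool[: k - 1]}
    cut |= {(v, u) for u, v in cut}

    # connected components of the whole tree minus cut edges
    seen: set[int] = set()
    components: list[set[str]] = []
    for start in tree.adjacency:
        if start in seen:
            continue
        comp_leaves: set[str] = set()
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            if node in tree.leaf_names:
                comp_leaves.add(tree.leaf_names[node])
            for nbr in tree.adjacency[node]:
                if nbr not in seen and (node, nbr) not in cut:
                    seen.add(nbr)
                    stack.append(nbr)
        if comp_leaves:
            components.append(comp_leaves)
    components.sort(key=lambda c: (-len(c), min(c)))
    out: dict[str, int] = {}
    for idx, comp in enumerate(components, start=1):
        for leaf in comp:
            out[leaf] = idx
    return out


def exon_intron_stats(gene_models: Sequence[GeneModel]) -> list[GeneStructureStat]:
    """Exon/intron counts and CDS length per gene model."""
    out = []
    for gm in gene_models:
        n_exons = len(gm.exon_intervals)
        out.append(
            GeneStructureStat(
                gene_id=gm.gene_id,
                exon_count=n_exons,
                intron_count=max(0, n_exons - 1),
                cds_length=gm.cds_length,
            )
        )
    return out
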