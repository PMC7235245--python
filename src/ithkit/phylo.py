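"""Per-patient evolutionary trees from SCNA and methylation distances.

Trees are distance-based: a neighbor-joining start (scikit-bio) refined by
nearest-neighbor-interchange moves under the balanced minimum evolution (BME)
criterion, with branch lengths by ordinary least squares (negatives clamped
to 0). SCNA and methylation matrices are combined into a consensus distance

    d0_ij = 0.5 * (d1_ij / max d1 + d2_ij / max d2)

falling back to the normalized SCNA term alone for pairs lacking methylation.
Congruence between the two data types is measured by the Spearman correlation
of pooled within-patient pairwise distances with a Mantel-style permutation
test, and tree-vs-tree similarity by the Robinson-Foulds distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj

from .ith import PairwiseDistances

__all__ = [
    "PhyloTree",
    "combine_distances",
    "build_tree",
    "congruence",
    "tree_distance",
]


# ---------------------------------------------------------------------------
# consensus distances


def combine_distances(
    d1: PairwiseDistances, d2: PairwiseDistances | None = None
) -> PairwiseDistances:
    """Consensus of SCNA and methylation distances after max-normalization.

    Both matrices are rescaled by their maximum entry so the two data types
    are comparable; pairs present in both are averaged, pairs with SCNA only
    keep the normalized SCNA term. Output entries lie in [0, 1].
    """
    v1 = d1.values
    m1 = v1.max()
    if m1 <= 0:
        raise ValueError("SCNA distance matrix is identically zero; cannot normalize")
    out = v1 / m1
    if d2 is not None:
        m2 = d2.values.max()
        if m2 <= 0:
            raise ValueError("methylation distance matrix is identically zero")
        pos2 = {s: i for i, s in enumerate(d2.sample_ids)}
        n = len(d1.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = d1.sample_ids[i], d1.sample_ids[j]
                if si in pos2 and sj in pos2:
                    val = 0.5 * (
                        v1[i, j] / m1 + d2.values[pos2[si], pos2[sj]] / m2
                    )
                    out[i, j] = out[j, i] = val
    return PairwiseDistances(list(d1.sample_ids), out, "consensus")


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency over leaves (sample ids) and internal ints."""

    leaves: list[str]
    adjacency: dict  # node -> set of neighbors
    branch_lengths: dict  # frozenset({a, b}) -> float
    root_on: str | None = None

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the frozenset of
        the side not containing the first leaf."""
        anchor = self.leaves[0]
        parts = set()
        for a, b in self._edges():
            side = self._leafset_beyond(a, b)
            if 1 < len(side) < len(self.leaves) - 1:
                if anchor in side:
                    side = set(self.leaves) - side
                parts.add(frozenset(side))
        return parts

    def _edges(self):
        seen = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                e = frozenset((a, b))
                if e not in seen:
                    seen.add(e)
                    yield a, b
        return

    def _leafset_beyond(self, a, b) -> set:
        """Leaves on b's side of edge (a, b)."""
        stack, seen, leaves = [b], {a, b}, set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                leaves.add(node)
            for nb in self.adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return leaves

    def to_newick(self) -> str:
        root = self._pick_root()
        s = self._newick_rec(root, None) + ";"
        return s

    def _pick_root(self):
        if self.root_on is not None:
            return self.root_on
        for node in self.adjacency:
            if not isinstance(node, str):
                return node
        return self.leaves[0]

    def _newick_rec(self, node, parent) -> str:
        children = [n for n in self.adjacency[node] if n != parent]
        label = node if isinstance(node, str) else ""
        if not children:
            body = str(label)
        else:
            inner = ",".join(
                self._newick_rec(c, node)
                + f":{self.branch_lengths.get(frozenset((node, c)), 0.0):.6g}"
                for c in children
            )
            body = f"({inner}){label}"
        return body

    def to_skbio(self) -> TreeNode:
        return TreeNode.read([self.to_newick()])


def _tree_from_skbio(t: TreeNode, leaves: list[str]) -> tuple[dict, dict]:
    """Adjacency (and edge lengths) from a scikit-bio tree, with a degree-2
    root suppressed so the topology is properly unrooted."""
    adjacency: dict = {}
    lengths: dict = {}
    counter = itertools.count()
    ids: dict = {}

    def node_id(n):
        if n.is_tip():
            return str(n.name)
        if id(n) not in ids:
            ids[id(n)] = next(counter)
        return ids[id(n)]

    for n in t.traverse(include_self=True):
        adjacency.setdefault(node_id(n), set())
    for n in t.traverse(include_self=False):
        a, b = node_id(n.parent), node_id(n)
        adjacency[a].add(b)
        adjacency[b].add(a)
        lengths[frozenset((a, b))] = float(n.length or 0.0)

    # suppress degree-2 nodes (rooted representations)
    changed = True
    while changed:
        changed = False
        for node, nbrs in list(adjacency.items()):
            if not isinstance(node, str) and len(nbrs) == 2:
                a, b = sorted(nbrs, key=str)
                la = lengths.pop(frozenset((node, a)), 0.0)
                lb = lengths.pop(frozenset((node, b)), 0.0)
                adjacency[a].discard(node)
                adjacency[b].discard(node)
                adjacency[a].add(b)
                adjacency[b].add(a)
                lengths[frozenset((a, b))] = la + lb
                del adjacency[node]
                changed = True
                break
    return adjacency, lengths


def _topological_distances(adjacency: dict, leaves: list[str]) -> np.ndarray:
    """Edge-count path lengths between all leaf pairs (BFS per leaf)."""
    n = len(leaves)
    pos = {s: i for i, s in enumerate(leaves)}
    t = np.zeros((n, n), dtype=int)
    for leaf in leaves:
        dist = {leaf: 0}
        stack = [leaf]
        while stack:
            node = stack.pop(0)
            for nb in adjacency[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    stack.append(nb)
        for other in leaves:
            t[pos[leaf], pos[other]] = dist[other]
    return t


def _bme_length(adjacency: dict, leaves: list[str], d: np.ndarray) -> float:
    """Pauplin's balanced tree length: sum over pairs of d_ij * 2^(1 - t_ij)."""
    t = _topological_distances(adjacency, leaves)
    iu = np.triu_indices(len(leaves), 1)
    return float(np.sum(d[iu] * np.exp2(1.0 - t[iu])))


def _nni_moves(adjacency: dict):
    """Yield (edge, swap) candidates: for each internal edge (u,v), the two
    exchanges of one neighbor-subtree of u with one of v."""
    for u in list(adjacency):
        if isinstance(u, str):
            continue
        for v in list(adjacency[u]):
            if isinstance(v, str) or str(u) > str(v):
                continue
            a_nb = [x for x in adjacency[u] if x != v]
            b_nb = [x for x in adjacency[v] if x != u]
            if len(a_nb) < 2 or len(b_nb) < 1:
                continue
            b = a_nb[1]
            for c in b_nb:
                yield (u, v, b, c)


def _apply_nni(adjacency: dict, u, v, b, c) -> None:
    adjacency[u].discard(b)
    adjacency[b].discard(u)
    adjacency[v].discard(c)
    adjacency[c].discard(v)
    adjacency[u].add(c)
    adjacency[c].add(u)
    adjacency[v].add(b)
    adjacency[b].add(v)


def _ols_branch_lengths(adjacency: dict, leaves: list[str], d: np.ndarray) -> dict:
    edges = []
    seen = set()
    for a, nbrs in adjacency.items():
        for b in nbrs:
            e = frozenset((a, b))
            if e not in seen:
                seen.add(e)
                edges.append(e)
    pos = {e: i for i, e in enumerate(edges)}
    n = len(leaves)
    rows, y = [], []
    # path between each leaf pair via BFS with parent tracking
    for i in range(n):
        for j in range(i + 1, n):
            path = _path(adjacency, leaves[i], leaves[j])
            row = np.zeros(len(edges))
            for a, b in zip(path[:-1], path[1:]):
                row[pos[frozenset((a, b))]] = 1.0
            rows.append(row)
            y.append(d[i, j])
    x, *_ = np.linalg.lstsq(np.vstack(rows), np.asarray(y), rcond=None)
    return {e: max(0.0, float(v)) for e, v in zip(edges, x)}


def _path(adjacency: dict, a, b) -> list:
    prev = {a: None}
    stack = [a]
    while stack:
        node = stack.pop(0)
        if node == b:
            break
        for nb in adjacency[node]:
            if nb not in prev:
                prev[nb] = node
                stack.append(nb)
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def build_tree(
    d: PairwiseDistances, root_on: str | None = None, max_nni_rounds: int = 20
) -> PhyloTree:
    """Balanced minimum-evolution tree from a distance matrix.

    Neighbor joining provides the starting topology; NNI hill-climbing on
    Pauplin's balanced tree length refines it; branch lengths are OLS
    estimates clamped at 0. ``root_on`` names a leaf (e.g. the normal
    reference sample) used as the display root of the Newick output.
    """
    ids = list(d.sample_ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 leaves for a nontrivial topology")
    if root_on is not None and root_on not in ids:
        raise ValueError(f"root_on sample {root_on!r} not among leaves")
    dm = SkbioDistanceMatrix(d.values, ids)
    start = nj(dm)
    adjacency, _ = _tree_from_skbio(start, ids)

    best = _bme_length(adjacency, ids, d.values)
    for _ in range(max_nni_rounds):
        improved = False
        for u, v, b, c in list(_nni_moves(adjacency)):
            # an earlier accepted move may have invalidated this candidate
            if (
                v not in adjacency[u]
                or b not in adjacency[u]
                or c not in adjacency[v]
            ):
                continue
            _apply_nni(adjacency, u, v, b, c)
            cand = _bme_length(adjacency, ids, d.values)
            if cand < best - 1e-12:
                best = cand
                improved = True
            else:
                _apply_nni(adjacency, u, v, c, b)  # revert
        if not improved:
            break

    lengths = _ols_branch_lengths(adjacency, ids, d.values)
    return PhyloTree(ids, adjacency, lengths, root_on=root_on)


# ---------------------------------------------------------------------------
# congruence


def congruence(
    d1_list: list[PairwiseDistances],
    d2_list: list[PairwiseDistances],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Spearman correlation of pooled within-patient pairwise distances.

    Significance by a Mantel-style permutation test: within each patient the
    sample labels of the second matrix are permuted and the pooled rho
    recomputed; p is two-sided on |rho|. With ``exhaustive=True`` (single
    patient, small k) every relabeling is enumerated and the p-value is
    exact. Also returns per-patient rho.
    """
    if len(d1_list) != len(d2_list):
        raise ValueError("matrix lists must pair up patient-by-patient")
    rng = np.random.default_rng(seed)

    def pooled_rho(perms=None) -> float:
        xs, ys = [], []
        for idx, (d1, d2) in enumerate(zip(d1_list, d2_list)):
            k = d1.k
            iu = np.triu_indices(k, 1)
            xs.append(d1.values[iu])
            v2 = d2.values
            if perms is not None:
                p = perms[idx]
                v2 = v2[np.ix_(p, p)]
            ys.append(v2[iu])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < 3:
            raise ValueError("need >= 3 pairs for a correlation")
        return float(stats.spearmanr(x, y).statistic)

    rho_obs = pooled_rho()
    per_patient = []
    for d1, d2 in zip(d1_list, d2_list):
        iu = np.triu_indices(d1.k, 1)
        if len(iu[0]) >= 3:
            per_patient.append(
                float(stats.spearmanr(d1.values[iu], d2.values[iu]).statistic)
            )
        else:
            per_patient.append(np.nan)

    if exhaustive:
        if len(d1_list) != 1:
            raise ValueError("exhaustive enumeration supports a single patient")
        k = d1_list[0].k
        if math.factorial(k) > 40320:
            raise ValueError("too many relabelings to enumerate; use sampling")
        hits = total = 0
        for perm in itertools.permutations(range(k)):
            total += 1
            if abs(pooled_rho([np.asarray(perm)])) >= abs(rho_obs) - 1e-12:
                hits += 1
        p = hits / total
    else:
        hits = 0
        for _ in range(n_perm):
            perms = [rng.permutation(d1.k) for d1 in d1_list]
            if abs(pooled_rho(perms)) >= abs(rho_obs) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return {"rho": rho_obs, "p": p, "per_patient_rho": per_patient}


# ---------------------------------------------------------------------------
# tree comparison


def tree_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Robinson-Foulds distance: raw bipartition symmetric difference and the
    value normalized by 2(n-3)."""
    if set(t1.leaves) != set(t2.leaves):
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    raw = len(b1 ^ b2)
    n = len(t1.leaves)
    denom = 2 * (n - 3)
    return raw, (raw / denom if denom > 0 else 0.0)
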