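"""Distance-based phylogeny and monophyly assessment.

Trees are :class:`dendropy.Tree` objects. Tree building is Saitou-Nei
neighbor joining over Poisson-corrected p-distances computed on the
(typically trimmed) alignment; it is a desk-scale stand-in for
maximum-likelihood inference, and externally inferred Newick trees are
accepted everywhere a tree is consumed. NJ is exact on additive distances,
which is what the tests exploit.

Determinism rules, fixed so reruns are byte-identical:

* ties in the Q criterion are broken by the smallest ``(i, j)`` pair in the
  current working-label order;
* a negative branch length produced by the join formulas is clamped to 0
  and the deficit is moved onto the sibling branch (total path length
  between the two joined nodes is preserved).

Monophyly on an unrooted tree is the bipartition criterion: a leaf subset
is monophyletic iff it (or its complement) is one side of the split
induced by some edge, or it is trivial (a singleton or all leaves).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .anchor_map import Alignment
from .seqio import GAP


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise PhyloError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhyloError("diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise PhyloError("distances must be nonnegative")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatched sites among columns ungapped in both rows."""
    if len(a) != len(b):
        raise PhyloError("aligned rows must have equal length")
    compared = mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x != GAP and y != GAP:
            compared += 1
            if x != y:
                mismatch += 1
    if compared == 0:
        raise PhyloError("no comparable (mutually ungapped) sites")
    return mismatch / compared


def poisson_distance(p: float, cap: float = 0.95) -> float:
    """Poisson multiple-hit correction -ln(1-p); p is capped (with a warning)
    so saturated pairs stay finite."""
    if p < 0:
        raise PhyloError("p-distance must be nonnegative")
    if p > cap:
        warnings.warn(
            f"p-distance {p:.3f} capped at {cap} before Poisson correction",
            RuntimeWarning,
            stacklevel=2,
        )
        p = cap
    return -math.log1p(-p)


def alignment_distance_matrix(
    aln: Alignment, correction: str = "poisson"
) -> DistanceMatrix:
    """Pairwise distances between alignment rows (``poisson`` or raw ``p``)."""
    if correction not in ("poisson", "p"):
        raise ValueError("correction must be 'poisson' or 'p'")
    ids = aln.ids
    n = len(ids)
    d = np.zeros((n, n))
    seqs = [r.seq for r in aln.rows]
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(seqs[i], seqs[j])
            d[i, j] = d[j, i] = poisson_distance(p) if correction == "poisson" else p
    return DistanceMatrix(labels=list(ids), d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating seed node)."""
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))  # indices into rows of d / entries of nodes

    def join(i_pos: int, j_pos: int) -> np.ndarray:
        """Join active entries at positions i_pos < j_pos into a new node."""
        i, j = active[i_pos], active[j_pos]
        r = len(active)
        di = d[i, [k for k in active]].sum()
        dj = d[j, [k for k in active]].sum()
        li = 0.5 * d[i, j] + (di - dj) / (2 * (r - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = li
        nj_.edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d_new = np.zeros((d.shape[0] + 1, d.shape[0] + 1))
        d_new[: d.shape[0], : d.shape[0]] = d
        d_new[-1, :-1] = new_row[:-1]
        d_new[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        nonlocal_active_update(i_pos, j_pos, d.shape[0])
        return d_new

    def nonlocal_active_update(i_pos: int, j_pos: int, new_index: int) -> None:
        # remove j first (higher position), then i, append the merged node
        del active[j_pos]
        del active[i_pos]
        active.append(new_index)

    while len(active) > 3:
        r = len(active)
        sums = {k: d[k, active].sum() for k in active}
        best: Optional[tuple[float, int, int]] = None
        for a_pos in range(r):
            for b_pos in range(a_pos + 1, r):
                i, j = active[a_pos], active[b_pos]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                # strict < keeps the earliest (i, j) in working order on ties
                if best is None or q < best[0] - 1e-12:
                    best = (q, a_pos, b_pos)
        assert best is not None
        d = join(best[1], best[2])

    # final trifurcation: three remaining nodes attach to one seed node
    i, j, k = active
    seed = dendropy.Node()
    lengths = {
        i: 0.5 * (d[i, j] + d[i, k] - d[j, k]),
        j: 0.5 * (d[j, i] + d[j, k] - d[i, k]),
        k: 0.5 * (d[k, i] + d[k, j] - d[i, j]),
    }
    for idx in (i, j, k):
        seed.add_child(nodes[idx])
        nodes[idx].edge.length = max(lengths[idx], 0.0)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _canonical(split: frozenset, all_leaves: frozenset) -> frozenset:
    """Side of the split not containing the lexicographically smallest leaf."""
    smallest = min(all_leaves)
    return frozenset(all_leaves - split) if smallest in split else frozenset(split)


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial leaf-set splits, one per internal edge, canonicalized."""
    leaves = frozenset(leaf_labels(tree))
    n = len(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= n - 2:
            splits.add(_canonical(below, leaves))
    return splits


def split_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Branch length keyed by the canonical split of each edge (pendant edges
    keyed by their leaf singleton's canonical form). Lengths of edges inducing
    the same split (e.g. the two root-adjacent edges of a rooted binary tree)
    are summed, so the map describes the unrooted tree."""
    leaves = frozenset(leaf_labels(tree))
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) in (0, len(leaves)):
            continue
        key = _canonical(below, leaves)
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """Bipartition criterion on the unrooted tree."""
    taxa = frozenset(taxa)
    leaves = frozenset(leaf_labels(tree))
    unknown = taxa - leaves
    if unknown:
        raise PhyloError(f"taxa not in tree: {sorted(unknown)}")
    if not taxa:
        raise PhyloError("taxa must be nonempty")
    # trivial splits: singletons and their complements are sides of pendant edges
    if len(taxa) in (1, len(leaves) - 1, len(leaves)):
        return True
    return _canonical(taxa, leaves) in bipartitions(tree)


def split_distance_to_monophyly(tree: dendropy.Tree, taxa: Iterable[str]) -> int:
    """Minimal number of mismatched leaves between ``taxa`` and the best
    split side of the tree (0 iff monophyletic). Pendant and trivial splits
    are included as candidate sides."""
    taxa = frozenset(taxa)
    leaves = frozenset(leaf_labels(tree))
    if taxa - leaves:
        raise PhyloError("taxa must be a subset of the tree's leaves")
    candidates: list[frozenset] = [leaves]
    candidates.extend(frozenset([lf]) for lf in leaves)
    candidates.extend(bipartitions(tree))
    best = len(leaves)
    for side in candidates:
        for s in (side, leaves - side):
            if s:
                best = min(best, len(s.symmetric_difference(taxa)))
    return best
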