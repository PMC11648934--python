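"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: splits are found by
cutting edges of a graph and running connectivity, not by subtree
traversal; counts are recomputed from first principles.
"""

from __future__ import annotations

from collections import deque

import dendropy


def edge_cut_splits(tree: dendropy.Tree, include_trivial: bool = False) -> set[frozenset]:
    """Leaf bipartitions by deleting one edge at a time from the tree's
    adjacency graph and collecting the leaves of one component. Trivial
    (pendant) splits are excluded unless requested."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    edges = []
    for node in nodes:
        if node.parent_node is not None:
            a, b = index[id(node)], index[id(node.parent_node)]
            adj[a].add(b)
            adj[b].add(a)
            edges.append((a, b))
    leaf_label = {
        index[id(n)]: n.taxon.label for n in nodes if n.is_leaf() and n.taxon
    }
    all_leaves = frozenset(leaf_label.values())
    n_leaves = len(all_leaves)
    smallest = min(all_leaves)

    splits: set[frozenset] = set()
    for a, b in edges:
        seen = {a}
        queue = deque([a])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if (cur, nb) in ((a, b), (b, a)):
                    continue
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        side = frozenset(leaf_label[i] for i in seen if i in leaf_label)
        keep = (
            1 <= len(side) <= n_leaves - 1
            if include_trivial
            else 2 <= len(side) <= n_leaves - 2
        )
        if keep:
            if smallest in side:
                side = all_leaves - side
            splits.add(side)
    return splits


def monophyletic_by_enumeration(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """Monophyly via exhaustive edge-cut split enumeration over every edge
    of the tree, pendant edges included."""
    leaves = {n.taxon.label for n in tree.leaf_node_iter()}
    taxa = set(taxa)
    if len(taxa) == len(leaves):
        return True
    for side in edge_cut_splits(tree, include_trivial=True):
        if taxa == set(side) or taxa == leaves - set(side):
            return True
    return False
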