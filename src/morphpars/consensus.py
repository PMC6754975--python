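"""Strict consensus and outgroup rooting.

The strict consensus of a set of trees on one leaf set is the tree whose
internal branches are exactly the non-trivial bipartitions shared by every
input tree; clades that differ between equally good trees dissolve into
polytomies.  Outgroup rooting orients an unrooted tree on the branch
separating the designated outgroup taxa from the ingroup, which is what
gives character-state changes a direction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .tree import PhyloTree, TreeError

__all__ = ["strict_consensus", "root_with_outgroup", "compare_trees"]


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions present in every input."""
    if not trees:
        raise TreeError("strict consensus of an empty tree set")
    taxa = trees[0].taxa()
    for t in trees[1:]:
        if t.taxa() != taxa:
            raise TreeError("trees have different leaf sets")
    shared = trees[0].bipartitions()
    for t in trees[1:]:
        shared = shared & t.bipartitions()
    return _tree_from_splits(taxa, shared)


def _tree_from_splits(
    taxa: frozenset[str], splits: Iterable[frozenset[str]]
) -> PhyloTree:
    """Build the (unique) tree realizing a compatible split set.

    Splits are normalized to the side excluding the reference taxon, so any
    two are nested or disjoint and form a laminar family.
    """
    sides = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
    t = PhyloTree()
    top = t.add_node()
    node_of: list[tuple[frozenset[str], int]] = []
    for side in sides:
        parent = top
        for other, nid in node_of:  # smallest strict superset seen so far
            if side < other:
                parent = nid
        n = t.add_node()
        t.add_edge(parent, n)
        node_of.append((side, n))
    for taxon in sorted(taxa):
        parent = top
        best: frozenset[str] | None = None
        for side, nid in node_of:
            if taxon in side and (best is None or side < best):
                best, parent = side, nid
        leaf = t.add_node(taxon)
        t.add_edge(parent, leaf)
    return t


def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root on the branch separating the outgroup from the ingroup.

    If the outgroup is not monophyletic on this topology, the root goes on
    the edge that best separates outgroup from ingroup (maximizing correctly
    placed taxa over both orientations) and the returned tree's
    ``outgroup_monophyletic`` flag is ``False``.
    """
    out = set(outgroup)
    taxa = tree.taxa()
    if not out:
        raise TreeError("empty outgroup")
    if not out < taxa:
        raise TreeError("outgroup must be a proper subset of the leaf set")
    ingroup = taxa - out

    best_edge, best_score = None, -1
    for u, v in tree.edges():
        side_u = tree.leafset_below(u, v)
        side_v = taxa - side_u
        for og_side in (side_u, side_v):
            score = len(out & og_side) + len(ingroup - og_side)
            if score > best_score:
                best_score, best_edge = score, (u, v)
    rooted = tree.copy()
    rooted.unroot()
    u, v = best_edge  # type: ignore[misc]
    if u not in rooted.adj or v not in rooted.adj[u]:
        # edge ids shifted when unrooting removed the old root; re-scan
        return root_with_outgroup(rooted, out)
    rooted.reroot_on_edge(u, v)
    rooted.outgroup_monophyletic = best_score == len(taxa)
    return rooted


def compare_trees(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson–Foulds symmetric-difference distance between topologies;
    0 iff the unrooted topologies are identical."""
    return a.symmetric_difference(b)
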