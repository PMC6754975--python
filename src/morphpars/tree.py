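"""Unrooted/rooted phylogenetic trees over taxon labels.

Trees are stored as an undirected adjacency map over integer node ids, with
leaves carrying taxon labels.  An unrooted tree has ``root is None``;
parsimony length is invariant to where a traversal starts, so any node can
serve as a traversal anchor.  Rooting (for outgroup polarity and ACCTRAN)
designates a degree-2 node inserted on an edge.

Topology identity is by bipartition set: two trees are the same unrooted
topology iff they induce the same non-trivial splits of the same leaf set.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["PhyloTree", "TreeError"]


class TreeError(ValueError):
    pass


class PhyloTree:
    """A possibly-multifurcating tree; see module docstring for conventions."""

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self.root: Optional[int] = None
        self._next_id = 0
        # set by root_with_outgroup; True/False once rooting was outgroup-aware
        self.outgroup_monophyletic: Optional[bool] = None

    # -- construction ------------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def remove_node(self, n: int) -> None:
        for nb in list(self.adj[n]):
            self.remove_edge(n, nb)
        del self.adj[n]
        self.labels.pop(n, None)

    @classmethod
    def star(cls, labels: Iterable[str]) -> "PhyloTree":
        """Unrooted star: one hub adjacent to every leaf."""
        t = cls()
        hub = t.add_node()
        for lab in labels:
            leaf = t.add_node(lab)
            t.add_edge(hub, leaf)
        return t

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {n: list(nbs) for n, nbs in self.adj.items()}
        t.labels = dict(self.labels)
        t.root = self.root
        t._next_id = self._next_id
        t.outgroup_monophyletic = self.outgroup_monophyletic
        return t

    # -- basic queries -----------------------------------------------------

    def nodes(self) -> list[int]:
        return list(self.adj)

    def leaves(self) -> list[int]:
        return [n for n in self.adj if n in self.labels]

    def taxa(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def degree(self, n: int) -> int:
        return len(self.adj[n])

    def neighbors(self, n: int) -> list[int]:
        return list(self.adj[n])

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self.labels and v not in self.labels
        ]

    def is_binary_unrooted(self) -> bool:
        return all(
            self.degree(n) == 3 for n in self.adj if n not in self.labels
        ) and self.root is None

    # -- traversal ---------------------------------------------------------

    def postorder(self, start: int | None = None) -> list[tuple[int, int]]:
        """Edges ``(node, parent)`` in postorder from ``start`` (or root).

        The start node itself appears last with parent ``-1``.
        """
        if start is None:
            start = self.root if self.root is not None else min(self.adj)
        order: list[tuple[int, int]] = []
        stack = [(start, -1)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        order.reverse()
        return order

    def parent_map(self) -> dict[int, int]:
        """node -> parent for the rooted orientation (root maps to -1)."""
        if self.root is None:
            raise TreeError("tree is unrooted")
        return {n: p for n, p in self.postorder(self.root)}

    def children_map(self) -> dict[int, list[int]]:
        if self.root is None:
            raise TreeError("tree is unrooted")
        ch: dict[int, list[int]] = {n: [] for n in self.adj}
        for n, p in self.postorder(self.root):
            if p != -1:
                ch[p].append(n)
        return ch

    def node_depths(self) -> dict[int, int]:
        if self.root is None:
            raise TreeError("tree is unrooted")
        depth = {self.root: 0}
        for n, p in reversed(self.postorder(self.root)):
            if p != -1:
                depth[n] = depth[p] + 1
        return depth

    # -- topology identity -------------------------------------------------

    def leafset_below(self, node: int, parent: int) -> frozenset[str]:
        acc: set[str] = set()
        stack = [(node, parent)]
        while stack:
            n, p = stack.pop()
            if n in self.labels:
                acc.add(self.labels[n])
            for nb in self.adj[n]:
                if nb != p:
                    stack.append((nb, n))
        return frozenset(acc)

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each normalized to the side not containing the
        lexicographically smallest taxon.  Rooting is ignored (a degree-2
        root contributes nothing beyond its underlying edge)."""
        all_taxa = self.taxa()
        if len(all_taxa) < 4:
            return frozenset()
        ref = min(all_taxa)
        splits: set[frozenset[str]] = set()
        for n, p in self.postorder(min(self.adj)):
            if p == -1 or n in self.labels:
                continue
            side = self.leafset_below(n, p)
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                splits.add(side)
        return frozenset(splits)

    def topology_key(self) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
        return (self.taxa(), self.bipartitions())

    def symmetric_difference(self, other: "PhyloTree") -> int:
        """Robinson-Foulds bipartition symmetric-difference distance."""
        if self.taxa() != other.taxa():
            raise TreeError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- surgery helpers ---------------------------------------------------

    def insert_node_on_edge(self, u: int, v: int) -> int:
        """Subdivide edge (u, v) with a new node and return its id."""
        self.remove_edge(u, v)
        w = self.add_node()
        self.add_edge(u, w)
        self.add_edge(w, v)
        return w

    def suppress_degree_two(self, keep: Iterable[int] = ()) -> None:
        """Remove internal degree-2 nodes, fusing their incident edges."""
        keep = set(keep)
        if self.root is not None:
            keep.add(self.root)
        for n in [n for n in list(self.adj) if n not in self.labels]:
            if n in keep or n not in self.adj:
                continue
            if len(self.adj[n]) == 2:
                a, b = self.adj[n]
                self.remove_node(n)
                self.add_edge(a, b)

    def reroot_on_edge(self, u: int, v: int) -> None:
        """Root the tree at a new degree-2 node subdividing edge (u, v).

        The tree must be unrooted (call :meth:`unroot` first); edge ids are
        unstable across unrooting, so re-pick the edge afterwards.
        """
        if self.root is not None:
            raise TreeError("tree already rooted; unroot() first")
        self.root = self.insert_node_on_edge(u, v)

    def unroot(self) -> None:
        if self.root is None:
            return
        r = self.root
        self.root = None
        if r not in self.labels and self.degree(r) == 2:
            a, b = self.adj[r]
            self.remove_node(r)
            self.add_edge(a, b)

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor of the given taxa (rooted trees)."""
        if self.root is None:
            raise TreeError("mrca requires a rooted tree")
        want = set(taxa)
        label_of = {lab: n for n, lab in self.labels.items()}
        missing = want - set(label_of)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        parent = self.parent_map()
        counts: dict[int, int] = {}
        below: dict[int, int] = {n: 0 for n in self.adj}
        for n, p in self.postorder(self.root):
            c = below[n] + (1 if self.labels.get(n) in want else 0)
            if p != -1:
                below[p] += c
            counts[n] = c
        # deepest node covering all target taxa
        depths = self.node_depths()
        cands = [n for n, c in counts.items() if c == len(want)]
        return max(cands, key=lambda n: (depths[n], -n))

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string (no branch lengths; labels quoted when needed)."""

        def q(label: str) -> str:
            if label and all(ch.isalnum() or ch == "_" for ch in label):
                return label
            return "'" + label.replace("'", "''") + "'"

        def render(node: int, parent: int) -> str:
            kids = [nb for nb in self.adj[node] if nb != parent]
            if not kids:
                return q(self.labels[node])
            inner = ",".join(render(k, node) for k in kids)
            lab = q(self.labels[node]) if node in self.labels else ""
            return f"({inner}){lab}"

        if self.root is not None:
            start = self.root
        else:
            # anchor at an internal node so the string reads as unrooted
            internal = [n for n in self.adj if n not in self.labels]
            start = min(internal) if internal else min(self.adj)
        return render(start, -1) + ";"

    @classmethod
    def from_newick(cls, s: str) -> "PhyloTree":
        """Parse a Newick string (via dendropy); degree-2 tops stay rooted."""
        dtree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=True
        )
        t = cls()

        def build(dnode, parent_id: int | None) -> None:
            label = dnode.taxon.label if dnode.taxon is not None else None
            nid = t.add_node(label)
            if parent_id is not None:
                t.add_edge(parent_id, nid)
            for ch in dnode.child_nodes():
                build(ch, nid)

        build(dtree.seed_node, None)
        top = min(t.adj)
        if top not in t.labels and t.degree(top) == 2:
            t.root = top
        return t

    def __repr__(self) -> str:
        kind = "rooted" if self.root is not None else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"
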