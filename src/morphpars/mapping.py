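"""ACCTRAN character-state reconstruction and homoplasy classification.

Among the many minimum-change assignments of ancestral states a character
usually admits, ACCTRAN (accelerated transformation) picks the one placing
changes as close to the root as possible, so a state is gained early and
reversed later rather than gained twice in parallel.  Here that preference
is made exact: each character is optimized by a dynamic program whose cost
is lexicographic in (number of changes, sum of change depths), so the
result is guaranteed minimal in steps and, among minimal reconstructions,
minimal in total root distance of its changes.  Remaining ties resolve
toward the parent's state, then the lowest state code; the root resolves
toward the unique outgroup state when there is one.

Classification follows standard usage on a fixed tree: a derived state with
a single origin and no reversal is non-homoplastic; multiple independent
origins make it convergent; a change back to a state carried by an ancestor
is a reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .parsimony import MAX_STATES, fitch_length
from .tree import PhyloTree, TreeError

__all__ = [
    "Change",
    "Reconstruction",
    "HomoplasyReport",
    "acctran_reconstruct",
    "classify_homoplasy",
    "count_origins",
    "annotate_internodes",
]

_BIG = 1 << 40
# scale factor separating the step count from the depth sum in the scalar
# DP cost; safe while total depth sum < 2^20
_K = 1 << 20


@dataclass(frozen=True)
class Change:
    """One state transition on a branch: parent node -> child node."""

    branch: tuple[int, int]
    char_index: int  # 1-based
    from_state: int
    to_state: int


@dataclass
class Reconstruction:
    """Per-node, per-character ACCTRAN state assignment on a rooted tree."""

    tree: PhyloTree
    matrix: CharacterMatrix
    states: dict[int, np.ndarray]  # node -> (n_chars,) int8 state codes
    changes: list[Change]

    def changes_for(self, char_index: int) -> list[Change]:
        return [c for c in self.changes if c.char_index == char_index]

    def node_state(self, node: int, char_index: int) -> int:
        return int(self.states[node][char_index - 1])


@dataclass
class HomoplasyReport:
    """(character, derived state) -> origin/reversal counts and class."""

    entries: dict[tuple[int, int], dict] = field(default_factory=dict)

    def classification(self, char_index: int, state: int) -> str:
        return self.entries[(char_index, state)]["classification"]

    def origins(self, char_index: int, state: int) -> int:
        if (char_index, state) not in self.entries:
            return 0
        return self.entries[(char_index, state)]["origins"]


def _outgroup_pref(matrix: CharacterMatrix) -> np.ndarray:
    """Per character, the unique outgroup state (or -1 if absent/ambiguous)."""
    pref = np.full(matrix.n_chars, -1, dtype=np.int8)
    if not matrix.outgroup:
        return pref
    sub = matrix.subset([t for t in matrix.outgroup if t in matrix.taxa])
    for j in range(matrix.n_chars):
        col = sub.cells[:, j]
        obs = set(int(s) for s in col[col >= 0])
        if len(obs) == 1:
            pref[j] = obs.pop()
    return pref


def acctran_reconstruct(tree: PhyloTree, matrix: CharacterMatrix) -> Reconstruction:
    """Minimum-change assignment with changes pushed root-ward (ACCTRAN).

    Requires a rooted binary tree; polytomies are refused because mapping
    belongs on each fully resolved most-parsimonious tree, not on a
    consensus.
    """
    if tree.root is None:
        raise TreeError("ACCTRAN requires a rooted tree (root_with_outgroup first)")
    for n in tree.adj:
        if n in tree.labels:
            continue
        want = 2 if n == tree.root else 3
        if tree.degree(n) != want:
            raise TreeError(
                "tree has a polytomy; reconstruct on a binary "
                "most-parsimonious tree rather than the consensus"
            )

    n_chars = matrix.n_chars
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    observed = [matrix.observed_states(j + 1) or [0] for j in range(n_chars)]
    depths = tree.node_depths()
    order = tree.postorder(tree.root)
    children = tree.children_map()

    # leaf allowance -> cost 0, else effectively infinite
    def leaf_cost(label: str) -> np.ndarray:
        try:
            row = matrix.cells[row_of[label]]
        except KeyError:
            raise TreeError(f"leaf {label!r} not in matrix") from None
        cost = np.full((n_chars, MAX_STATES), _BIG, dtype=np.int64)
        for j in range(n_chars):
            if row[j] >= 0:
                cost[j, row[j]] = 0
            else:
                cost[j, observed[j]] = 0
        return cost

    # DP up pass: cost[v][j, s] = minimal (steps * K + depth-sum) of the
    # subtree at v with v forced to state s at character j
    cost: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node in tree.labels:
            cost[node] = leaf_cost(tree.labels[node])
            continue
        acc = np.zeros((n_chars, MAX_STATES), dtype=np.int64)
        for ch in children[node]:
            c = cost[ch]
            change_cost = c.min(axis=1, keepdims=True) + _K + depths[ch]
            acc = acc + np.minimum(c, change_cost)
        cost[node] = acc

    pref = _outgroup_pref(matrix)
    states: dict[int, np.ndarray] = {}

    # root choice among minimal-cost states
    root_cost = cost[tree.root]
    root_states = np.empty(n_chars, dtype=np.int8)
    minima = root_cost.min(axis=1)
    for j in range(n_chars):
        cands = np.flatnonzero(root_cost[j] == minima[j])
        if pref[j] in cands:
            root_states[j] = pref[j]
        else:
            root_states[j] = cands[0]
    states[tree.root] = root_states

    # preorder resolution: prefer the parent's state among optimal choices,
    # then the lowest code
    changes: list[Change] = []
    for node, parent in reversed(order):
        if parent == -1:
            continue
        ps = states[parent]
        c = cost[node]
        edge_extra = _K + depths[node]
        node_states = np.empty(n_chars, dtype=np.int8)
        for j in range(n_chars):
            parent_state = int(ps[j])
            totals = c[j] + edge_extra
            totals[parent_state] = c[j, parent_state]  # no change, no cost
            best = totals.min()
            cands = np.flatnonzero(totals == best)
            s = parent_state if parent_state in cands else int(cands[0])
            node_states[j] = s
            if s != parent_state:
                changes.append(Change((parent, node), j + 1, parent_state, s))
        states[node] = node_states

    recon = Reconstruction(tree, matrix, states, changes)
    # conservation guard: per-character change counts must equal Fitch steps
    _, per_steps = fitch_length(tree, matrix)
    got = np.zeros(n_chars, dtype=np.int64)
    for ch in changes:
        got[ch.char_index - 1] += 1
    if not np.array_equal(got, per_steps):  # pragma: no cover - internal guard
        raise AssertionError("ACCTRAN change counts disagree with Fitch steps")
    return recon


def classify_homoplasy(recon: Reconstruction) -> HomoplasyReport:
    """Count origins and reversals of every derived state on the tree."""
    tree = recon.tree
    parent = tree.parent_map()
    report = HomoplasyReport()
    anc_cache: dict[int, list[int]] = {}

    def ancestors(node: int) -> list[int]:
        if node not in anc_cache:
            chain = []
            p = parent[node]
            while p != -1:
                chain.append(p)
                p = parent[p]
            anc_cache[node] = chain
        return anc_cache[node]

    for ch in recon.changes:
        key = (ch.char_index, ch.to_state)
        entry = report.entries.setdefault(
            key, {"origins": 0, "reversals": 0, "classification": ""}
        )
        entry["origins"] += 1
        u = ch.branch[0]  # parent end of the branch carrying the change
        j = ch.char_index - 1
        states_above = {int(recon.states[a][j]) for a in ancestors(u)}
        if ch.to_state in states_above:
            entry["reversals"] += 1
    for entry in report.entries.values():
        conv = entry["origins"] > 1
        rev = entry["reversals"] > 0
        if conv and rev:
            entry["classification"] = "both"
        elif conv:
            entry["classification"] = "convergent"
        elif rev:
            entry["classification"] = "reversal"
        else:
            entry["classification"] = "non-homoplastic"
    return report


def count_origins(recon: Reconstruction, char_index: int, state: int) -> int:
    """Number of branches on which ``state`` arises for this character."""
    return sum(
        1
        for ch in recon.changes
        if ch.char_index == char_index and ch.to_state == state
    )


def annotate_internodes(
    tree: PhyloTree, recon: Reconstruction
) -> dict[tuple[int, int], list[dict]]:
    """Map every change to its branch, with its homoplasy class attached."""
    if tree is not recon.tree and tree.bipartitions() != recon.tree.bipartitions():
        raise TreeError("annotation tree differs from reconstruction tree")
    report = classify_homoplasy(recon)
    out: dict[tuple[int, int], list[dict]] = {}
    for ch in recon.changes:
        out.setdefault(ch.branch, []).append(
            {
                "char": ch.char_index,
                "from": ch.from_state,
                "to": ch.to_state,
                "classification": report.classification(ch.char_index, ch.to_state),
            }
        )
    return out


def annotation_table(recon: Reconstruction) -> pd.DataFrame:
    """Flat per-change table (branch, character, from, to, class)."""
    rows = []
    annotated = annotate_internodes(recon.tree, recon)
    for branch, items in sorted(annotated.items()):
        clade = recon.tree.leafset_below(branch[1], branch[0])
        for item in items:
            rows.append(
                {
                    "branch": f"{branch[0]}->{branch[1]}",
                    "clade_size": len(clade),
                    "smallest_clade_taxon": min(clade),
                    **item,
                }
            )
    return pd.DataFrame(rows)


def render_cladogram(recon: Reconstruction) -> str:
    """Plain-text cladogram with per-branch change annotations."""
    tree = recon.tree
    annotated = annotate_internodes(tree, recon)
    out = StringIO()

    def mark(items: list[dict]) -> str:
        if not items:
            return ""
        bits = []
        for it in items:
            tag = {"non-homoplastic": "*", "convergent": "~", "reversal": "!", "both": "~!"}[
                it["classification"]
            ]
            bits.append(f"{it['char']}:{it['from']}>{it['to']}{tag}")
        return "  [" + ", ".join(bits) + "]"

    def walk(node: int, parent: int, prefix: str, is_last: bool) -> None:
        branch = (parent, node)
        label = tree.labels.get(node, "")
        conn = "`-- " if is_last else "|-- "
        ann = mark(annotated.get(branch, []))
        if parent == -1:
            out.write(label + "\n")
        else:
            out.write(prefix + conn + label + ann + "\n")
        kids = [nb for nb in tree.adj[node] if nb != parent]
        ext = "    " if is_last else "|   "
        for i, k in enumerate(kids):
            walk(k, node, prefix + ("" if parent == -1 else ext), i == len(kids) - 1)

    walk(tree.root, -1, "", True)
    out.write("changes: * unique, ~ convergent, ! reversal\n")
    return out.getvalue()
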