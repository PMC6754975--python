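"""Parsimony scoring: Fitch length, step bounds, and ensemble CI/RI.

All characters are unordered (any state-to-state change costs one step) and
equally weighted.  Equivocal cells — missing or inapplicable — are expanded
to the full set of states *observed* in that character, so they can never
force a step; states never observed in a character cannot reduce its length
and are excluded from the expansion.

State sets are bitmasks packed per character into a ``uint8`` vector, so a
Fitch node combination is three vectorized operations over all characters
at once.  :func:`sankoff_length` is a deliberately separate dynamic program
over per-state cost vectors kept as an independent check on the Fitch path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .tree import PhyloTree, TreeError

__all__ = [
    "FitchEncoding",
    "EnsembleStats",
    "fitch_length",
    "sankoff_length",
    "char_min_steps",
    "char_max_steps",
    "ensemble_indices",
    "character_diagnostics",
]

_BIG = np.int32(1 << 20)
MAX_STATES = 5


class FitchEncoding:
    """Bitmask encoding of a character matrix for set-based scoring.

    ``masks[i, j]`` has bit ``s`` set iff taxon ``i`` may carry state ``s``
    at character ``j``; equivocal cells carry every observed state.
    """

    def __init__(self, matrix: CharacterMatrix) -> None:
        self.matrix = matrix
        cells = matrix.cells
        n_taxa, n_chars = cells.shape
        state_bits = np.where(cells >= 0, np.left_shift(1, np.maximum(cells, 0)), 0)
        observed = np.bitwise_or.reduce(state_bits, axis=0).astype(np.uint8)
        # all-equivocal characters: park every cell on an arbitrary single
        # state so they contribute zero steps everywhere
        equiv_mask = np.where(observed > 0, observed, 1).astype(np.uint8)
        self.masks = np.where(cells >= 0, state_bits, equiv_mask).astype(np.uint8)
        self.observed_masks = observed
        self.n_chars = n_chars
        self._row = {t: i for i, t in enumerate(matrix.taxa)}

    def leaf_mask(self, label: str) -> np.ndarray:
        try:
            return self.masks[self._row[label]]
        except KeyError:
            raise KeyError(f"leaf {label!r} not present in character matrix") from None


def _as_encoding(data: Union[CharacterMatrix, FitchEncoding]) -> FitchEncoding:
    return data if isinstance(data, FitchEncoding) else FitchEncoding(data)


def _combine(sets: list[np.ndarray], steps: np.ndarray) -> np.ndarray:
    """Sequential Fitch combination; increments ``steps`` in place."""
    cur = sets[0]
    for nxt in sets[1:]:
        inter = cur & nxt
        empty = inter == 0
        if empty.any():
            steps += empty
            inter = np.where(empty, cur | nxt, inter)
        cur = inter
    return cur


def fitch_length(
    tree: PhyloTree, data: Union[CharacterMatrix, FitchEncoding]
) -> tuple[int, np.ndarray]:
    """Fitch parsimony length of ``tree`` and its per-character breakdown.

    Exact for binary trees at any rooting; polytomies are scored by
    sequential pairwise combination of child state sets.  Returns
    ``(total_steps, per_character_steps)``.
    """
    enc = _as_encoding(data)
    steps = np.zeros(enc.n_chars, dtype=np.int32)
    sets: dict[int, np.ndarray] = {}
    for node, parent in tree.postorder():
        inputs: list[np.ndarray] = []
        if node in tree.labels:
            inputs.append(enc.leaf_mask(tree.labels[node]))
        inputs.extend(
            sets.pop(nb) for nb in tree.adj[node] if nb != parent
        )
        sets[node] = _combine(inputs, steps) if inputs else None  # type: ignore[arg-type]
    return int(steps.sum()), steps


def sankoff_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Unit-cost Sankoff dynamic program: minimal total changes over all
    ancestral state assignments.  Equals :func:`fitch_length` on binary
    trees; exact on polytomies too.  Kept structurally independent of the
    Fitch bitmask path as a cross-check oracle.
    """
    cells = matrix.cells
    n_chars = matrix.n_chars
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    observed = [
        set(matrix.observed_states(j + 1)) or {0} for j in range(n_chars)
    ]

    def leaf_cost(label: str) -> np.ndarray:
        try:
            row = cells[row_of[label]]
        except KeyError:
            raise KeyError(f"leaf {label!r} not present in character matrix") from None
        cost = np.full((n_chars, MAX_STATES), _BIG, dtype=np.int32)
        for j in range(n_chars):
            if row[j] >= 0:
                cost[j, row[j]] = 0
            else:
                for s in observed[j]:
                    cost[j, s] = 0
        return cost

    costs: dict[int, np.ndarray] = {}
    for node, parent in tree.postorder():
        kids = [nb for nb in tree.adj[node] if nb != parent]
        if node in tree.labels:
            acc = leaf_cost(tree.labels[node])
            for k in kids:
                c = costs.pop(k)
                acc = acc + np.minimum(c, c.min(axis=1, keepdims=True) + 1)
        elif kids:
            acc = np.zeros((n_chars, MAX_STATES), dtype=np.int32)
            for k in kids:
                c = costs.pop(k)
                acc = acc + np.minimum(c, c.min(axis=1, keepdims=True) + 1)
        else:  # isolated node
            acc = np.zeros((n_chars, MAX_STATES), dtype=np.int32)
        costs[node] = acc
    top = costs[tree.postorder()[-1][0]]
    return int(top.min(axis=1).sum())


# ---------------------------------------------------------------------------
# Per-character step bounds
# ---------------------------------------------------------------------------

def char_min_steps(matrix: CharacterMatrix, char_index: int) -> int:
    """Minimum conceivable steps: one fewer than the observed state count."""
    return max(len(matrix.observed_states(char_index)) - 1, 0)


def char_max_steps(matrix: CharacterMatrix, char_index: int) -> int:
    """Maximum conceivable steps: the star-tree value, scored-taxon count
    minus the modal state's frequency."""
    col = matrix.cells[:, char_index - 1]
    col = col[col >= 0]
    if col.size <= 1:
        return 0
    counts = np.bincount(col)
    return int(col.size - counts.max())


def _is_informative(m: int, g: int) -> bool:
    # a character whose minimum equals its star-tree maximum cannot vary in
    # steps across topologies and carries no grouping signal
    return m != g


# ---------------------------------------------------------------------------
# Ensemble indices
# ---------------------------------------------------------------------------

@dataclass
class EnsembleStats:
    """Summed step quantities and the homoplasy indices built from them.

    ``ci = sum_min / sum_obs`` (consistency index) and
    ``ri = (sum_max - sum_obs) / (sum_max - sum_min)`` (retention index);
    ``ri`` is ``None`` when its denominator is zero.
    """

    sum_min: int
    sum_obs: int
    sum_max: int
    ci: float | None
    ri: float | None
    per_char: list[tuple[int, int, int]]
    includes_uninformative: bool = True


def ensemble_indices(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
) -> EnsembleStats:
    """Compute CI and RI of ``tree`` on ``matrix``.

    ``include_uninformative=False`` drops parsimony-uninformative characters
    from the sums (both reporting conventions are in circulation).
    """
    missing = tree.taxa() - set(matrix.taxa)
    if missing:
        raise TreeError(f"tree leaves not in matrix: {sorted(missing)}")
    if set(matrix.taxa) - tree.taxa():
        raise TreeError("tree must contain every matrix taxon for ensemble indices")
    _, per_steps = fitch_length(tree, matrix)
    per_char: list[tuple[int, int, int]] = []
    smin = sobs = smax = 0
    for j in range(matrix.n_chars):
        m = char_min_steps(matrix, j + 1)
        g = char_max_steps(matrix, j + 1)
        s = int(per_steps[j])
        per_char.append((m, s, g))
        if include_uninformative or _is_informative(m, g):
            smin += m
            sobs += s
            smax += g
    ci = smin / sobs if sobs > 0 else None
    ri = (smax - sobs) / (smax - smin) if smax > smin else None
    return EnsembleStats(smin, sobs, smax, ci, ri, per_char, include_uninformative)


def character_diagnostics(tree: PhyloTree, matrix: CharacterMatrix) -> pd.DataFrame:
    """Per-character table: index, m, s, g, per-character ci/ri, informative."""
    stats = ensemble_indices(tree, matrix)
    rows = []
    for d, (m, s, g) in zip(matrix.chardefs, stats.per_char):
        rows.append(
            {
                "char": d.index,
                "subject": d.subject,
                "min_steps": m,
                "obs_steps": s,
                "max_steps": g,
                "ci": m / s if s > 0 else np.nan,
                "ri": (g - s) / (g - m) if g > m else np.nan,
                "informative": _is_informative(m, g),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Directional (per-edge) machinery shared by tree search and branch collapse
# ---------------------------------------------------------------------------

def directional_fitch(
    tree: PhyloTree, enc: FitchEncoding
) -> tuple[dict[tuple[int, int], np.ndarray], dict[tuple[int, int], np.ndarray]]:
    """Fitch state sets and step counts for every *directed* edge.

    ``D[(u, v)]`` is the downpass state-set vector of the component
    containing ``u`` when edge (u, v) is cut, and ``W[(u, v)]`` its
    per-character step count.  Computed in two passes, O(edges) combines.
    """
    D: dict[tuple[int, int], np.ndarray] = {}
    W: dict[tuple[int, int], np.ndarray] = {}
    order = tree.postorder(min(tree.adj))

    def gather(node: int, excl: int) -> tuple[list[np.ndarray], np.ndarray]:
        inputs: list[np.ndarray] = []
        steps = np.zeros(enc.n_chars, dtype=np.int32)
        if node in tree.labels:
            inputs.append(enc.leaf_mask(tree.labels[node]))
        for nb in tree.adj[node]:
            if nb != excl:
                inputs.append(D[(nb, node)])
                steps = steps + W[(nb, node)]
        return inputs, steps

    # up pass: child-side sets
    for node, parent in order:
        if parent == -1:
            continue
        inputs, steps = gather(node, parent)
        D[(node, parent)] = _combine(inputs, steps)
        W[(node, parent)] = steps
    # down pass: parent-side sets (parents before children)
    for node, parent in reversed(order):
        if parent == -1:
            continue
        inputs, steps = gather(parent, node)
        D[(parent, node)] = _combine(inputs, steps)
        W[(parent, node)] = steps
    return D, W


def branch_min_lengths(
    tree: PhyloTree, enc: FitchEncoding
) -> dict[tuple[int, int], int]:
    """For each edge, the minimum total length it takes over all
    most-parsimonious reconstructions (0 means the branch can collapse)."""
    D, _ = directional_fitch(tree, enc)
    out: dict[tuple[int, int], int] = {}
    for u, v in tree.edges():
        out[(u, v)] = int(np.count_nonzero((D[(u, v)] & D[(v, u)]) == 0))
    return out


def directional_sankoff(
    tree: PhyloTree, enc: FitchEncoding
) -> dict[tuple[int, int], np.ndarray]:
    """Unit-cost per-state cost vectors for every directed edge.

    ``C[(u, v)][j, s]`` is the minimal step count of the component
    containing ``u`` (edge (u, v) cut) when its edge-end node is forced to
    state ``s`` at character ``j``.
    """
    n_chars = enc.n_chars
    bit = np.left_shift(1, np.arange(MAX_STATES, dtype=np.uint8)).astype(np.uint8)

    def leaf_cost(label: str) -> np.ndarray:
        mask = enc.leaf_mask(label)
        allowed = (mask[:, None] & bit[None, :]) > 0
        return np.where(allowed, 0, _BIG).astype(np.int32)

    def contrib(c: np.ndarray) -> np.ndarray:
        return np.minimum(c, c.min(axis=1, keepdims=True) + 1)

    C: dict[tuple[int, int], np.ndarray] = {}
    order = tree.postorder(min(tree.adj))

    def gather(node: int, excl: int) -> np.ndarray:
        acc = (
            leaf_cost(tree.labels[node])
            if node in tree.labels
            else np.zeros((n_chars, MAX_STATES), dtype=np.int32)
        )
        for nb in tree.adj[node]:
            if nb != excl:
                acc = acc + contrib(C[(nb, node)])
        return acc

    for node, parent in order:
        if parent != -1:
            C[(node, parent)] = gather(node, parent)
    for node, parent in reversed(order):
        if parent != -1:
            C[(parent, node)] = gather(parent, node)
    return C


def branch_change_possibility(
    tree: PhyloTree, enc: FitchEncoding
) -> dict[tuple[int, int], np.ndarray]:
    """Per edge, a boolean vector: can some most-parsimonious reconstruction
    place a change of character j on this edge?  Used by the strictest
    branch-collapse rule (collapse only when no MPR puts a change there)."""
    C = directional_sankoff(tree, enc)
    eye = np.eye(MAX_STATES, dtype=bool)
    out: dict[tuple[int, int], np.ndarray] = {}
    for u, v in tree.edges():
        a, b = C[(u, v)], C[(v, u)]
        grid = a[:, :, None] + b[:, None, :]
        same = np.where(eye[None, :, :], grid, _BIG).min(axis=(1, 2))
        diff = np.where(eye[None, :, :], _BIG, grid).min(axis=(1, 2)) + 1
        best = np.minimum(same, diff)
        out[(u, v)] = diff == best
    return out
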