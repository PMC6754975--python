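"""Synthetic trees and discrete character matrices with known truth.

Characters evolve under a minimal Mk-style process on a random topology:
a uniform-random root state, and on every branch an independent chance
``change_prob`` of jumping to a uniformly chosen *different* state.  There
are no branch lengths — the parsimony pipeline is topology-only, so a
branch-homogeneous change probability is the simplest generator with a
tunable amount of homoplasy.  Missing and inapplicable tokens are injected
independently per cell; inapplicability is unconditional (not hierarchical
character dependency), since scoring treats both as equivocal anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import INAPPLICABLE, MISSING, CharacterMatrix, _default_chardefs
from .tree import PhyloTree, TreeError

__all__ = ["SimConfig", "random_topology", "simulate_matrix", "study_like_matrix"]


@dataclass
class SimConfig:
    """Generator settings.

    ``states_per_char`` may be a single int or a per-character list (2-5
    states).  ``change_prob`` is the per-branch probability of a state
    transition; 0.02 on a small tree gives nearly homoplasy-free data,
    while values above ~0.1 approach the saturation seen in real
    morphological matrices.
    """

    n_taxa: int = 38
    n_chars: int = 48
    states_per_char: int | list[int] = 2
    change_prob: float = 0.07
    missing_frac: float = 0.0
    inapplicable_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4 or self.n_chars < 1:
            raise ValueError("need n_taxa >= 4 and n_chars >= 1")
        for p in (self.change_prob, self.missing_frac, self.inapplicable_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def states_list(self) -> list[int]:
        if isinstance(self.states_per_char, int):
            ks = [self.states_per_char] * self.n_chars
        else:
            ks = list(self.states_per_char)
            if len(ks) != self.n_chars:
                raise ValueError("states_per_char list length != n_chars")
        if any(not 2 <= k <= 5 for k in ks):
            raise ValueError("states per character must be 2..5")
        return ks


def random_topology(n_taxa: int, seed: int | np.random.Generator = 0) -> PhyloTree:
    """Uniform random unrooted binary topology with leaves ``t1..tn``.

    Built by sequential insertion on a uniformly chosen branch; every
    topology has exactly one construction history for a fixed leaf order,
    so the draw is uniform over the (2n-5)!! topologies.
    """
    if n_taxa < 3:
        raise TreeError("need at least 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = PhyloTree.star([f"t{i + 1}" for i in range(3)])
    for i in range(3, n_taxa):
        edges = tree.edges()
        x, y = edges[rng.integers(len(edges))]
        w = tree.insert_node_on_edge(x, y)
        leaf = tree.add_node(f"t{i + 1}")
        tree.add_edge(w, leaf)
    return tree


def simulate_matrix(tree: PhyloTree, config: SimConfig) -> CharacterMatrix:
    """Evolve characters down ``tree`` under the config's jump process."""
    rng = np.random.default_rng(config.seed)
    ks = config.states_list()
    n_chars = config.n_chars
    anchor = min(n for n in tree.adj if n not in tree.labels) if any(
        n not in tree.labels for n in tree.adj
    ) else min(tree.adj)
    order = tree.postorder(anchor)

    kmax = np.array(ks)
    states: dict[int, np.ndarray] = {}
    # walk root-ward to tip-ward: reversed postorder is parent-before-child
    for node, parent in reversed(order):
        if parent == -1:
            states[node] = (rng.random(n_chars) * kmax).astype(np.int8)
            continue
        s = states[parent].copy()
        jump = rng.random(n_chars) < config.change_prob
        if jump.any():
            # uniform among the k-1 other states
            offset = 1 + (rng.random(n_chars) * (kmax - 1)).astype(np.int8)
            s[jump] = (s[jump] + offset[jump]) % kmax[jump]
        states[node] = s

    taxa = sorted(tree.labels.values(), key=lambda lab: (len(lab), lab))
    label_node = {lab: n for n, lab in tree.labels.items()}
    cells = np.stack([states[label_node[lab]] for lab in taxa]).astype(np.int8)

    # equivocal-token injection
    u = rng.random(cells.shape)
    cells = np.where(u < config.inapplicable_frac, INAPPLICABLE, cells)
    cells = np.where(
        (u >= config.inapplicable_frac)
        & (u < config.inapplicable_frac + config.missing_frac),
        MISSING,
        cells,
    ).astype(np.int8)

    chardefs = [
        type(d)(d.index, d.subject, tuple(str(s) for s in range(k)))
        for d, k in zip(_default_chardefs(n_chars), ks)
    ]
    return CharacterMatrix(taxa, chardefs, cells)


# state-count mix of the bundled study matrix: mostly binary, a third of the
# characters with 3 states, single 4- and 5-state characters
_STUDY_STATE_MIX = [2] * 31 + [3] * 15 + [4, 5]


def study_like_matrix(seed: int = 0) -> tuple[PhyloTree, CharacterMatrix]:
    """A truth tree plus a matrix shaped like the bundled study data:
    38 taxa x 48 characters, mixed 2-5 state counts, ~9% inapplicable
    cells, no missing cells, and moderate homoplasy."""
    rng = np.random.default_rng(seed)
    tree = random_topology(38, rng)
    mix = list(_STUDY_STATE_MIX)
    rng.shuffle(mix)
    config = SimConfig(
        n_taxa=38,
        n_chars=48,
        states_per_char=mix,
        change_prob=0.07,
        missing_frac=0.0,
        inapplicable_frac=0.09,
        seed=int(rng.integers(1 << 31)),
    )
    return tree, simulate_matrix(tree, config)
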