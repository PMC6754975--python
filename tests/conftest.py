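import numpy as np
import pytest

import morphpars as mp
from morphpars.simulate import SimConfig, random_topology, simulate_matrix


@pytest.fixture(scope="session")
def study():
    return mp.load_study_matrix()


@pytest.fixture
def quartet_matrix():
    # two characters cleanly favoring ((A,B),(C,D))
    return mp.parse_tsv("A\t0\t0\nB\t0\t0\nC\t1\t1\nD\t1\t1")


def make_instance(n_taxa, n_chars, seed, states=3, change_prob=0.3, inapplicable=0.0):
    """Random (tree, matrix) pair for oracle cross-checks."""
    tree = random_topology(n_taxa, seed)
    matrix = simulate_matrix(
        tree,
        SimConfig(
            n_taxa=n_taxa,
            n_chars=n_chars,
            states_per_char=states,
            change_prob=change_prob,
            inapplicable_frac=inapplicable,
            seed=seed + 7919,
        ),
    )
    return tree, matrix


def brute_force_min_steps(tree, matrix, char_index):
    """Independent oracle: minimum changes over *all* ancestral (and
    equivocal-leaf) state assignments, by exhaustive enumeration."""
    from itertools import product

    j = char_index - 1
    observed = matrix.observed_states(char_index) or [0]
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    free, fixed = [], {}
    for node in tree.nodes():
        if node in tree.labels:
            cell = int(matrix.cells[row_of[tree.labels[node]], j])
            if cell >= 0:
                fixed[node] = cell
            else:
                free.append(node)
        else:
            free.append(node)
    edges = tree.edges()
    best = None
    for combo in product(observed, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        steps = sum(1 for u, v in edges if assign[u] != assign[v])
        if best is None or steps < best:
            best = steps
    return best
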