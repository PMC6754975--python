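"""Strict consensus, outgroup rooting, ACCTRAN mapping, homoplasy classes."""

from itertools import product

import pytest

import morphpars as mp
from morphpars.mapping import annotation_table

from conftest import make_instance


class TestStrictConsensus:
    def test_identity(self):
        t = mp.PhyloTree.from_newick("((A,B),(C,(D,E)));")
        t.unroot()
        assert mp.strict_consensus([t]).bipartitions() == t.bipartitions()

    def test_conflicting_clade_collapses(self):
        a = mp.PhyloTree.from_newick("((A,B),(C,(D,E)));")
        b = mp.PhyloTree.from_newick("((A,B),(D,(C,E)));")
        cons = mp.strict_consensus([a, b])
        assert frozenset({"A", "B"}) not in cons.bipartitions()  # side w/o ref
        # shared clade kept: the split separating {C,D,E}
        assert frozenset({"C", "D", "E"}) in cons.bipartitions()
        # conflicting resolutions gone
        assert frozenset({"D", "E"}) not in cons.bipartitions()
        assert frozenset({"C", "E"}) not in cons.bipartitions()

    def test_order_invariant(self):
        trees = [make_instance(7, 1, s)[0] for s in range(4)]
        fwd = mp.strict_consensus(trees).bipartitions()
        rev = mp.strict_consensus(trees[::-1]).bipartitions()
        assert fwd == rev

    def test_consensus_splits_subset_of_every_input(self):
        trees = [make_instance(8, 1, s)[0] for s in range(5)]
        cons = mp.strict_consensus(trees).bipartitions()
        for t in trees:
            assert cons <= t.bipartitions()

    def test_leafset_mismatch(self):
        with pytest.raises(mp.TreeError):
            mp.strict_consensus([make_instance(6, 1, 0)[0], make_instance(7, 1, 0)[0]])


class TestRootWithOutgroup:
    def test_single_taxon_outgroup(self):
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        t.unroot()
        r = mp.root_with_outgroup(t, {"A"})
        assert r.outgroup_monophyletic
        kids = r.neighbors(r.root)
        sides = [r.leafset_below(k, r.root) for k in kids]
        assert frozenset({"A"}) in sides

    def test_pair_outgroup(self):
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        t.unroot()
        r = mp.root_with_outgroup(t, {"A", "B"})
        sides = [r.leafset_below(k, r.root) for k in r.neighbors(r.root)]
        assert frozenset({"A", "B"}) in sides

    def test_nonmonophyletic_outgroup_flagged(self):
        t = mp.PhyloTree.from_newick("((A,C),(B,D));")
        t.unroot()
        r = mp.root_with_outgroup(t, {"A", "B"})
        assert r.outgroup_monophyletic is False

    def test_outgroup_equal_leafset_rejected(self):
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        with pytest.raises(mp.TreeError):
            mp.root_with_outgroup(t, {"A", "B", "C", "D"})


def brute_force_acctran(tree, matrix, char_index):
    """Enumerate every minimum-change assignment and keep those whose
    changes sit maximally root-ward (minimal total change depth)."""
    j = char_index - 1
    observed = matrix.observed_states(char_index) or [0]
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    parent = tree.parent_map()
    depths = tree.node_depths()
    nodes = tree.nodes()
    free, fixed = [], {}
    for node in nodes:
        if node in tree.labels:
            cell = int(matrix.cells[row_of[tree.labels[node]], j])
            if cell >= 0:
                fixed[node] = cell
            else:
                free.append(node)
        else:
            free.append(node)
    edges = [(p, n) for n, p in parent.items() if p != -1]
    best = []
    best_cost = None
    for combo in product(observed, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        steps = sum(1 for p, n in edges if assign[p] != assign[n])
        depth_sum = sum(depths[n] for p, n in edges if assign[p] != assign[n])
        cost = (steps, depth_sum)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best = [assign]
        elif cost == best_cost:
            best.append(assign)
    return best_cost, best


class TestAcctran:
    @pytest.mark.parametrize("seed", range(6))
    def test_change_counts_equal_fitch_steps(self, seed):
        tree, matrix = make_instance(7, 8, seed, change_prob=0.3, inapplicable=0.1)
        rooted = mp.root_with_outgroup(tree, {"t1"})
        recon = mp.acctran_reconstruct(rooted, matrix)
        _, per = mp.fitch_length(rooted, matrix)
        for jj in range(matrix.n_chars):
            assert len(recon.changes_for(jj + 1)) == per[jj]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rootward_maximal_enumeration(self, seed):
        """On every small case the assignment must be minimal in steps and,
        among minimal assignments, minimal in summed change depth."""
        tree, matrix = make_instance(6, 5, seed, states=3, change_prob=0.35,
                                     inapplicable=0.1)
        rooted = mp.root_with_outgroup(tree, {"t1"})
        recon = mp.acctran_reconstruct(rooted, matrix)
        depths = rooted.node_depths()
        parent = rooted.parent_map()
        for jj in range(matrix.n_chars):
            (steps, depth_sum), optima = brute_force_acctran(rooted, matrix, jj + 1)
            got_changes = recon.changes_for(jj + 1)
            assert len(got_changes) == steps
            assert sum(depths[c.branch[1]] for c in got_changes) == depth_sum
            got_assign = {n: recon.node_state(n, jj + 1) for n in rooted.nodes()}
            assert got_assign in optima

    def test_leaf_states_respect_matrix(self):
        tree, matrix = make_instance(6, 6, 3, change_prob=0.3)
        rooted = mp.root_with_outgroup(tree, {"t1"})
        recon = mp.acctran_reconstruct(rooted, matrix)
        row_of = {t: i for i, t in enumerate(matrix.taxa)}
        for node, lab in rooted.labels.items():
            for jj in range(matrix.n_chars):
                cell = int(matrix.cells[row_of[lab], jj])
                if cell >= 0:
                    assert recon.node_state(node, jj + 1) == cell

    def test_polytomy_refused(self):
        t = mp.PhyloTree.star(["A", "B", "C", "D"])
        hub = [n for n in t.adj if n not in t.labels][0]
        leaf = t.leaves()[0]
        t.root = t.insert_node_on_edge(hub, leaf)
        _, matrix = make_instance(4, 3, 0)
        matrix.taxa = ["A", "B", "C", "D"]
        matrix._row = {x: i for i, x in enumerate(matrix.taxa)}
        with pytest.raises(mp.TreeError, match="polytomy"):
            mp.acctran_reconstruct(t, matrix)

    def test_unrooted_refused(self):
        tree, matrix = make_instance(6, 4, 0)
        with pytest.raises(mp.TreeError, match="rooted"):
            mp.acctran_reconstruct(tree, matrix)


class TestHomoplasyClassification:
    def _recon(self, rows, newick, outgroup):
        matrix = mp.parse_tsv(rows)
        t = mp.PhyloTree.from_newick(newick)
        t.unroot()
        rooted = mp.root_with_outgroup(t, outgroup)
        return mp.acctran_reconstruct(rooted, matrix)

    def test_single_origin_non_homoplastic(self):
        recon = self._recon(
            "O\t0\nA\t0\nB\t1\nC\t1", "(O,(A,(B,C)));", {"O"}
        )
        rep = mp.classify_homoplasy(recon)
        assert rep.classification(1, 1) == "non-homoplastic"
        assert mp.count_origins(recon, 1, 1) == 1

    def test_convergence_counted(self):
        # state 1 in two distant tips forces two origins
        recon = self._recon(
            "O\t0\nA\t1\nB\t0\nC\t1\nD\t0", "(O,((A,B),(C,D)));", {"O"}
        )
        rep = mp.classify_homoplasy(recon)
        assert mp.count_origins(recon, 1, 1) == 2
        assert rep.classification(1, 1) == "convergent"

    def test_reversal_detected(self):
        # gain of 1 below the outgroup, then loss back to 0 in a nested tip
        recon = self._recon(
            "O\t0\nA\t1\nB\t1\nC\t0\nD\t1", "(O,(A,(B,(C,D))));", {"O"}
        )
        rep = mp.classify_homoplasy(recon)
        assert rep.entries[(1, 0)]["reversals"] >= 1
        assert rep.classification(1, 0) == "reversal"

    def test_absent_state_has_zero_origins(self):
        recon = self._recon("O\t0\nA\t0\nB\t1\nC\t1", "(O,(A,(B,C)));", {"O"})
        assert mp.count_origins(recon, 1, 2) == 0


class TestAnnotation:
    def test_zero_change_matrix_empty(self):
        m = mp.parse_tsv("A\t0\nB\t0\nC\t0\nD\t0")
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        recon = mp.acctran_reconstruct(t, m)
        assert mp.annotate_internodes(t, recon) == {}

    @pytest.mark.parametrize("seed", range(4))
    def test_total_annotations_equal_length(self, seed):
        tree, matrix = make_instance(7, 10, seed, change_prob=0.3)
        rooted = mp.root_with_outgroup(tree, {"t1"})
        recon = mp.acctran_reconstruct(rooted, matrix)
        annotated = mp.annotate_internodes(rooted, recon)
        total = sum(len(v) for v in annotated.values())
        assert total == mp.fitch_length(rooted, matrix)[0]
        assert len(annotation_table(recon)) == total
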