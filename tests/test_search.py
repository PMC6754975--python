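"""Stepwise addition, TBR neighborhoods, heuristic and exhaustive search."""

import dendropy
import numpy as np
import pytest

import morphpars as mp
from morphpars.parsimony import FitchEncoding
from morphpars.search import _bisections, nni_neighbors
from morphpars.simulate import SimConfig, random_topology, simulate_matrix

from conftest import make_instance


class TestStepwiseAddition:
    def test_three_taxa_star(self, quartet_matrix):
        held = mp.stepwise_addition(quartet_matrix, ["A", "B", "C"], hold=5)
        assert len(held) == 1
        assert held[0].taxa() == frozenset("ABC")

    def test_four_taxa_best_ranked_first(self, quartet_matrix):
        held = mp.stepwise_addition(quartet_matrix, ["A", "B", "C", "D"], hold=3)
        assert held[0].bipartitions() == frozenset({frozenset({"C", "D"})})

    def test_too_few_taxa(self, quartet_matrix):
        with pytest.raises(mp.TreeError):
            mp.stepwise_addition(quartet_matrix, ["A", "B"], hold=5)

    @pytest.mark.parametrize("seed", range(4))
    def test_held_trees_not_better_than_optimum(self, seed):
        tree, matrix = make_instance(8, 25, seed, change_prob=0.25)
        opt = mp.exhaustive_search(matrix).best_length
        order = list(matrix.taxa)
        np.random.default_rng(seed).shuffle(order)
        for t in mp.stepwise_addition(matrix, order, hold=5):
            assert mp.fitch_length(t, matrix)[0] >= opt


def _restriction(newick: str, taxa: set, tns) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    keep = [tx for tx in tns if tx.label in taxa]
    return t.extract_tree_with_taxa(taxa=keep)


def _same_topology(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


def _tbr_oracle_neighbors(tree: mp.PhyloTree) -> set:
    """Independent characterization: T' is one bisect+reconnect product of T
    iff some branch of T splits the leaves so that T' induces the same
    subtree topology on both sides.  Enumerates every topology and tests
    that condition with dendropy restrictions."""
    n = tree.n_leaves
    taxa = sorted(tree.taxa())
    splits = []
    for u, v in tree.edges():
        side = set(tree.leafset_below(u, v))
        splits.append((side, set(taxa) - side))
    tns = dendropy.TaxonNamespace([dendropy.Taxon(label=t) for t in taxa])
    base = tree.to_newick()
    base_restrictions = {}
    hits = set()

    def all_topologies(k):
        t = mp.PhyloTree.star(taxa[:3])
        out = []

        def rec(i):
            if i == k:
                out.append((t.bipartitions(), t.to_newick()))
                return
            for x, y in list(t.edges()):
                w = t.insert_node_on_edge(x, y)
                leaf = t.add_node(taxa[i])
                t.add_edge(w, leaf)
                rec(i + 1)
                t.remove_node(leaf)
                t.remove_node(w)
                t.add_edge(x, y)

        rec(3)
        return out

    def has_split(key, side):
        if not 2 <= len(side) <= n - 2:
            return True  # trivial split, always present
        fs = frozenset(side)
        comp = frozenset(taxa) - fs
        return fs in key or comp in key

    for key, nw in all_topologies(n):
        for side_a, side_b in splits:
            # the new connecting edge recreates this bipartition, so a TBR
            # product must contain it in addition to both induced subtrees
            if not has_split(key, side_a):
                continue
            ok = True
            for side in (side_a, side_b):
                if len(side) < 3:
                    continue
                fs = frozenset(side)
                if fs not in base_restrictions:
                    base_restrictions[fs] = _restriction(base, side, tns)
                if not _same_topology(
                    _restriction(nw, side, tns), base_restrictions[fs]
                ):
                    ok = False
                    break
            if ok:
                hits.add(key)
                break
    return hits


class TestTbrNeighbors:
    def test_quartet_reaches_all_topologies(self):
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        t.unroot()
        keys = {n.bipartitions() for n in mp.tbr_neighbors(t)}
        assert len(keys) == 3  # both alternatives plus the identity

    def test_contains_nni_neighbors(self):
        t = random_topology(5, 2)
        tbr = {n.bipartitions() for n in mp.tbr_neighbors(t)}
        nni = {n.bipartitions() for n in nni_neighbors(t)}
        assert nni <= tbr

    def test_neighbor_set_matches_restriction_oracle(self):
        t = random_topology(6, 5)
        got = {n.bipartitions() for n in mp.tbr_neighbors(t)}
        assert got == _tbr_oracle_neighbors(t)

    def test_requires_binary_unrooted(self):
        t = mp.PhyloTree.star(["A", "B", "C", "D"])
        with pytest.raises(mp.TreeError):
            next(mp.tbr_neighbors(t))

    @pytest.mark.parametrize("seed", range(3))
    def test_fast_join_score_equals_rescore(self, seed):
        """Every fragment-join score must equal a from-scratch Fitch score
        of the materialized neighbor."""
        tree, matrix = make_instance(7, 10, seed, change_prob=0.3)
        enc = FitchEncoding(matrix)
        from morphpars.search import _join

        for f1, f2 in _bisections(tree):
            for p1, s1, w1 in f1.scored_points(enc):
                for p2, s2, w2 in f2.scored_points(enc):
                    ln = w1 + w2 + int(((s1 & s2) == 0).sum())
                    nt = _join(f1, p1, f2, p2)
                    assert ln == mp.fitch_length(nt, enc)[0]


class TestExhaustiveSearch:
    def test_topology_counts(self):
        _, m4 = make_instance(4, 5, 0)
        assert mp.exhaustive_search(m4).n_evaluated == 3
        _, m7 = make_instance(7, 5, 0)
        assert mp.exhaustive_search(m7).n_evaluated == 945

    def test_refuses_out_of_range(self):
        _, m = make_instance(10, 3, 0)
        with pytest.raises(mp.TreeError):
            mp.exhaustive_search(m)

    def test_optimum_trees_score_best_length(self):
        _, m = make_instance(7, 12, 3, change_prob=0.3)
        res = mp.exhaustive_search(m)
        for t in res.binary_trees:
            assert mp.sankoff_length(t, m) == res.best_length


class TestHeuristicSearch:
    def test_perfect_data_recovers_truth(self):
        tree = random_topology(6, 11)
        matrix = simulate_matrix(
            tree, SimConfig(n_taxa=6, n_chars=40, change_prob=0.05, seed=11)
        )
        res = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=5, seed=1))
        opt = mp.exhaustive_search(matrix)
        assert res.best_length == opt.best_length
        if opt.best_length == sum(
            mp.char_min_steps(matrix, j + 1) for j in range(matrix.n_chars)
        ):
            assert tree.bipartitions() in {t.bipartitions() for t in res.binary_trees}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_optimum(self, seed):
        _, matrix = make_instance(8, 20, seed, change_prob=0.3)
        res = mp.heuristic_search(
            matrix, mp.SearchConfig(n_replicates=5, hold=3, seed=seed)
        )
        assert res.best_length == mp.exhaustive_search(matrix).best_length

    def test_reported_trees_rescore_to_best(self):
        _, matrix = make_instance(8, 15, 17, change_prob=0.35)
        res = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=4, seed=17))
        for t in res.binary_trees:
            assert mp.sankoff_length(t, matrix) == res.best_length

    def test_reproducible(self):
        _, matrix = make_instance(8, 15, 23, change_prob=0.3)
        cfg = mp.SearchConfig(n_replicates=6, seed=99)
        a = mp.heuristic_search(matrix, cfg)
        b = mp.heuristic_search(matrix, cfg)
        assert a.best_length == b.best_length
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]
        assert a.log == b.log

    def test_max_trees_truncation_flagged(self):
        _, matrix = make_instance(8, 6, 31, change_prob=0.4)
        res = mp.heuristic_search(
            matrix, mp.SearchConfig(n_replicates=3, seed=31, max_trees=1)
        )
        full = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=3, seed=31))
        if len(full.binary_trees) > 1:
            assert res.truncated

    def test_spr_not_better_than_tbr(self):
        _, matrix = make_instance(8, 15, 41, change_prob=0.3)
        tbr = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=4, seed=5))
        spr = mp.heuristic_search(
            matrix, mp.SearchConfig(n_replicates=4, seed=5, swap="spr")
        )
        assert spr.best_length >= tbr.best_length


class TestCollapseAndDedupe:
    def test_reroot_duplicates_collapse_to_one(self):
        _, matrix = make_instance(6, 10, 1)
        t = random_topology(6, 1)
        u = t.copy()
        e = u.edges()[2]
        u.reroot_on_edge(*e)
        assert len(mp.collapse_and_dedupe([t, u], matrix, "none")) == 1

    def test_unsupported_branch_becomes_polytomy(self):
        m = mp.parse_tsv("A\t0\nB\t0\nC\t0\nD\t1")
        t = mp.PhyloTree.from_newick("((A,B),(C,D));")
        t.unroot()
        (collapsed,) = mp.collapse_and_dedupe([t], m, "min_length_zero")
        assert collapsed.bipartitions() == frozenset()

    def test_max_rule_collapses_subset_of_min_rule(self):
        _, matrix = make_instance(8, 10, 13, change_prob=0.25)
        res = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=3, seed=13))
        by_min = mp.collapse_and_dedupe(res.binary_trees, matrix, "min_length_zero")
        by_max = mp.collapse_and_dedupe(res.binary_trees, matrix, "max_length_zero")
        # every branch the max rule collapses the min rule collapses too, so
        # min-rule topologies are coarsenings and can only merge further
        assert len(by_min) <= len(by_max) <= len(res.binary_trees)
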