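import numpy as np
import pytest

import oracles
from tepars.parsimony import Column, fitch_length
from tepars.search import (
    SearchConfig,
    SearchError,
    bootstrap,
    collapse_unsupported,
    mp_search,
    root_on_outgroup,
    strict_consensus,
)
from tepars.trees import PhyloTree


class ColumnsMatrix:
    def __init__(self, columns, taxa):
        self._columns = list(columns)
        self.taxa = list(taxa)
        self.total_characters = len(self._columns)

    def columns(self):
        return list(self._columns)


def random_matrix(labels, n_columns, rng, **kw):
    return ColumnsMatrix(
        [oracles.random_column(labels, rng, **kw) for _ in range(n_columns)],
        labels,
    )


def exhaustive_best(matrix):
    best = None
    best_trees = []
    for tree in oracles.exhaustive_unrooted_topologies(matrix.taxa):
        length = sum(fitch_length(tree, c) for c in matrix.columns())
        if best is None or length < best:
            best, best_trees = length, [tree]
        elif length == best:
            best_trees.append(tree)
    return best_trees, best


class TestMpSearch:
    def test_four_taxon_equals_exhaustive(self, rng):
        labels = list("ABCD")
        for trial in range(8):
            matrix = random_matrix(labels, 12, rng)
            config = SearchConfig(n_addition_replicates=6, seed=trial)
            found, length = mp_search(matrix, config)
            expected_trees, expected = exhaustive_best(matrix)
            assert length == expected
            found_topos = {frozenset(t.bipartitions()) for t in found}
            expected_topos = {
                frozenset(t.bipartitions()) for t in expected_trees
            }
            assert found_topos == expected_topos

    def test_six_taxon_length_equals_exhaustive(self, rng):
        labels = list("ABCDEF")
        matrix = random_matrix(labels, 15, rng)
        _found, length = mp_search(
            matrix, SearchConfig(n_addition_replicates=8, swap="TBR", seed=3)
        )
        _trees, expected = exhaustive_best(matrix)
        assert length == expected

    def test_recovers_generating_topology(self, fixture_study):
        from tepars.assembly import concatenate

        combined = concatenate(
            fixture_study.morphology,
            fixture_study.partitions,
            fixture_study.catalog,
        )
        trees, _length = mp_search(
            combined, SearchConfig(n_addition_replicates=3, seed=5)
        )
        true_splits = fixture_study.true_tree.bipartitions()
        assert any(t.bipartitions() == true_splits for t in trees)

    def test_doubling_matrix_doubles_length_same_optima(self, rng):
        labels = list("ABCDE")
        matrix = random_matrix(labels, 10, rng)
        doubled = ColumnsMatrix(matrix.columns() * 2, labels)
        config = SearchConfig(n_addition_replicates=6, seed=9)
        t1, l1 = mp_search(matrix, config)
        t2, l2 = mp_search(doubled, config)
        assert l2 == 2 * l1
        assert {frozenset(t.bipartitions()) for t in t1} == {
            frozenset(t.bipartitions()) for t in t2
        }

    def test_deterministic_given_seed(self, rng):
        matrix = random_matrix(list("ABCDEF"), 10, rng)
        config = SearchConfig(n_addition_replicates=4, seed=11)
        r1 = mp_search(matrix, config)
        r2 = mp_search(matrix, config)
        assert r1[1] == r2[1]
        assert [t.to_newick() for t in r1[0]] == [t.to_newick() for t in r2[0]]

    def test_fewer_than_four_taxa_rejected(self):
        matrix = ColumnsMatrix([], list("ABC"))
        with pytest.raises(SearchError, match="at least 4"):
            mp_search(matrix, SearchConfig())


class TestCollapseUnsupported:
    def test_unique_change_retained(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        matrix = ColumnsMatrix(
            [
                Column(
                    states={
                        "A": frozenset({0}),
                        "B": frozenset({0}),
                        "C": frozenset({1}),
                        "D": frozenset({1}),
                    },
                    nstates=2,
                )
            ],
            list("ABCD"),
        )
        collapsed = collapse_unsupported(tree, matrix)
        assert collapsed.bipartitions() == {frozenset({"C", "D"})} or (
            collapsed.bipartitions() == {frozenset({"A", "B"})}
        ) or len(collapsed.bipartitions()) == 1

    def test_constant_data_collapses_to_star(self):
        tree = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        const = Column(
            states={t: frozenset({0}) for t in "ABCDE"}, nstates=2
        )
        matrix = ColumnsMatrix([const] * 4, list("ABCDE"))
        collapsed = collapse_unsupported(tree, matrix)
        assert collapsed.bipartitions() == set()

    def test_matches_bruteforce_zero_length_branch_rule(self, rng):
        labels = list("ABCDEF")
        for _ in range(10):
            tree = oracles.random_tree(labels, rng)
            columns = [
                oracles.random_column(labels, rng, ambiguous=False)
                for _ in range(4)
            ]
            matrix = ColumnsMatrix(columns, labels)
            collapsed = collapse_unsupported(tree, matrix)
            # oracle: an internal branch survives iff some column has a
            # change on it in *every* optimal labeling; for the two
            # root-child edges (one unrooted edge) the test is whether
            # some optimal labeling gives both children the same state
            expected = set()
            all_leaves = frozenset(labels)
            for node in tree.postorder():
                if node.is_leaf or node.parent is None:
                    continue
                forced = False
                for column in columns:
                    best = oracles.brute_force_length(tree, column)
                    free = False
                    for a, cost in oracles.enumerate_labelings(tree, column):
                        if cost != best:
                            continue
                        if (
                            node.parent is tree.root
                            and len(tree.root.children) == 2
                        ):
                            c1, c2 = tree.root.children
                            if a[id(c1)] == a[id(c2)]:
                                free = True
                                break
                        elif a[id(node.parent)] == a[id(node)]:
                            free = True
                            break
                    if not free:
                        forced = True
                        break
                if forced:
                    side = tree.leafset(node)
                    if min(all_leaves) in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        expected.add(side)
            assert collapsed.bipartitions() == expected

    def test_preserves_tree_length(self, rng):
        labels = list("ABCDEF")
        tree = oracles.random_tree(labels, rng)
        matrix = ColumnsMatrix(
            [oracles.random_column(labels, rng) for _ in range(6)], labels
        )
        collapsed = collapse_unsupported(tree, matrix)
        before = sum(fitch_length(tree, c) for c in matrix.columns())
        after = sum(fitch_length(collapsed, c) for c in matrix.columns())
        assert before == after


class TestStrictConsensus:
    def test_idempotent(self):
        t = PhyloTree.from_newick("((A,B),(C,(D,E)));", rooted=False)
        cons = strict_consensus([t, t.copy()])
        assert cons.bipartitions() == t.bipartitions()

    def test_single_shared_split(self):
        t1 = PhyloTree.from_newick("((A,B),(C,(D,E)));", rooted=False)
        t2 = PhyloTree.from_newick("((A,B),(D,(C,E)));", rooted=False)
        cons = strict_consensus([t1, t2])
        # hand-computed intersection: only the A|B vs rest split is shared
        assert cons.bipartitions() == {frozenset({"C", "D", "E"})}

    def test_disjoint_resolutions_give_star(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D),E);", rooted=False)
        t2 = PhyloTree.from_newick("((A,C),(B,D),E);", rooted=False)
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == set()

    def test_mismatched_leafsets_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));", rooted=False)
        t2 = PhyloTree.from_newick("((A,B),(C,E));", rooted=False)
        with pytest.raises(SearchError, match="identical leaf sets"):
            strict_consensus([t1, t2])


class TestBootstrap:
    def _congruent_matrix(self, labels, n_support):
        support = Column(
            states={
                t: frozenset({0 if t in ("A", "B") else 1}) for t in labels
            },
            nstates=2,
        )
        noise = Column(
            states={t: frozenset({0, 1}) for t in labels}, nstates=2
        )
        return ColumnsMatrix([support] * n_support + [noise], labels)

    def test_unconflicted_split_has_high_support(self):
        labels = list("ABCDEF")
        matrix = self._congruent_matrix(labels, 30)
        table = bootstrap(
            matrix, SearchConfig(n_addition_replicates=3, seed=1), n_reps=40
        )
        split = frozenset({"C", "D", "E", "F"})  # complement of {A,B}
        assert table.get(split, 0.0) >= 95.0

    def test_single_column_support_all_or_nothing(self):
        labels = list("ABCD")
        matrix = self._congruent_matrix(labels, 1)
        matrix = ColumnsMatrix(matrix.columns()[:1], labels)
        table = bootstrap(
            matrix, SearchConfig(n_addition_replicates=2, seed=2), n_reps=25
        )
        for percent in table.values():
            assert 0.0 <= percent <= 100.0

    def test_deterministic(self, rng):
        matrix = random_matrix(list("ABCDE"), 12, rng)
        config = SearchConfig(n_addition_replicates=2, seed=7)
        assert bootstrap(matrix, config, 10) == bootstrap(matrix, config, 10)

    def test_invalid_rep_count(self, rng):
        matrix = random_matrix(list("ABCDE"), 5, rng)
        with pytest.raises(SearchError, match="n_reps"):
            bootstrap(matrix, SearchConfig(), 0)


class TestRootOnOutgroup:
    def test_outgroup_becomes_basal(self):
        tree = PhyloTree.from_newick("((A,B),(C,(D,E)));", rooted=False)
        rooted = root_on_outgroup(tree, "C")
        sides = {rooted.leafset(c) for c in rooted.root.children}
        assert frozenset({"C"}) in sides

    def test_already_rooted_on_outgroup_unchanged(self):
        tree = PhyloTree.from_newick("(A,((B,C),(D,E)));")
        rooted = root_on_outgroup(tree, "A")
        assert rooted.bipartitions() == tree.bipartitions()

    def test_missing_label_raises(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=False)
        with pytest.raises(Exception, match="not found"):
            root_on_outgroup(tree, "Z")

    def test_rerooting_keeps_length(self, rng):
        labels = list("ABCDEF")
        tree = oracles.random_tree(labels, rng)
        column = oracles.random_column(labels, rng)
        rooted = root_on_outgroup(tree, "F")
        assert fitch_length(rooted, column) == fitch_length(tree, column)
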