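import numpy as np
import pytest

import oracles
from tepars.asr import (
    ASRError,
    reconstruct,
    stem_state,
    transformations,
)
from tepars.catalog import (
    INAPPLICABLE,
    MISSING,
    CharacterCatalog,
    CharacterDefinition,
    InapplicabilityCondition,
    matrix_from_rows,
)
from tepars.synthdata import SimConfig, simulate_morphology, simulate_tree
from tepars.trees import PhyloTree


def simple_catalog(n_chars=1, k=2):
    return CharacterCatalog(
        characters=[
            CharacterDefinition(
                char_id=i + 1,
                locus=f"c{i + 1}",
                statement=f"character {i + 1}",
                states=tuple((j, f"s{j}") for j in range(k)),
            )
            for i in range(n_chars)
        ]
    )


FIVE = "(((A,B),C),(D,E));"


class TestReconstruct:
    def test_constant_character(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog()
        matrix = matrix_from_rows({t: [1] for t in "ABCDE"}, [1])
        result = reconstruct(tree, matrix, cat)
        for nid, node in result.node_ids.items():
            assert result.states[nid][1] == frozenset({1})
        assert transformations(result) == []

    def test_five_taxon_hand_case_matches_enumeration(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog(k=3)
        scores = {"A": 0, "B": 1, "C": 1, "D": 2, "E": 2}
        matrix = matrix_from_rows({t: [s] for t, s in scores.items()}, [1])
        result = reconstruct(tree, matrix, cat)
        from tepars.parsimony import Column

        column = Column(
            states={t: frozenset({s}) for t, s in scores.items()}, nstates=3
        )
        expected, _best = oracles.brute_force_mpr(tree, column)
        for nid, node in result.node_ids.items():
            if not node.is_leaf:
                assert result.states[nid][1] == expected[id(node)]

    def test_leaf_scores_never_altered(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog(k=2)
        scores = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        matrix = matrix_from_rows({t: [s] for t, s in scores.items()}, [1])
        result = reconstruct(tree, matrix, cat)
        for nid, node in result.node_ids.items():
            if node.is_leaf:
                assert result.states[nid][1] == frozenset({scores[node.label]})

    def test_missing_leaf_gets_full_set(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog(k=3)
        matrix = matrix_from_rows(
            {"A": [0], "B": [MISSING], "C": [0], "D": [0], "E": [0]}, [1]
        )
        result = reconstruct(tree, matrix, cat)
        leaf_id = result.node_id_of(result.tree.find_leaf("B"))
        assert result.states[leaf_id][1] == frozenset({0, 1, 2})

    def test_invalid_matrix_refused(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = CharacterCatalog(
            characters=[
                CharacterDefinition(
                    char_id=1, locus="ctrl", statement="controller",
                    states=((0, "absent"), (1, "present")),
                ),
                CharacterDefinition(
                    char_id=2, locus="dep", statement="dependent",
                    states=((0, "a"), (1, "b")),
                    inapplicable_if=(
                        InapplicabilityCondition(1, frozenset({0})),
                    ),
                ),
            ]
        )
        matrix = matrix_from_rows(
            {t: [0, 1] for t in "ABCDE"}, [1, 2]
        )  # char 2 scored where inapplicable
        with pytest.raises(ASRError, match="validation"):
            reconstruct(tree, matrix, cat)

    def test_polytomy_refused_not_silently_resolved(self):
        tree = PhyloTree.from_newick("((A,B),C,(D,E));")
        cat = simple_catalog()
        matrix = matrix_from_rows({t: [0] for t in "ABCDE"}, [1])
        with pytest.raises(ASRError, match="resolve"):
            reconstruct(tree, matrix, cat)

    def test_inapplicable_context_annotated(self):
        # controller reconstructed as "absent" everywhere -> dependent
        # flagged at every node
        tree = PhyloTree.from_newick(FIVE)
        cat = CharacterCatalog(
            characters=[
                CharacterDefinition(
                    char_id=1, locus="ctrl", statement="controller",
                    states=((0, "absent"), (1, "present")),
                ),
                CharacterDefinition(
                    char_id=2, locus="dep", statement="dependent",
                    states=((0, "a"), (1, "b")),
                    inapplicable_if=(
                        InapplicabilityCondition(1, frozenset({0})),
                    ),
                ),
            ]
        )
        matrix = matrix_from_rows(
            {t: [0, INAPPLICABLE] for t in "ABCDE"}, [1, 2]
        )
        result = reconstruct(tree, matrix, cat)
        internal_ids = [
            nid for nid, n in result.node_ids.items() if not n.is_leaf
        ]
        assert all(
            (nid, 2) in result.inapplicable_context for nid in internal_ids
        )


class TestTransformations:
    def test_single_change_on_cherry(self):
        tree = PhyloTree.from_newick("(((A,B),C),(D,E));")
        cat = simple_catalog()
        matrix = matrix_from_rows(
            {"A": [1], "B": [1], "C": [0], "D": [0], "E": [0]}, [1]
        )
        result = reconstruct(tree, matrix, cat)
        records = transformations(result)
        assert len(records) == 1
        rec = records[0]
        assert rec.parent_states == frozenset({0})
        assert rec.child_states == frozenset({1})
        changed = result.node_ids[rec.node_id]
        assert result.tree.leafset(changed) == frozenset({"A", "B"})

    def test_order_is_preorder_then_char(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog(n_chars=2)
        matrix = matrix_from_rows(
            {"A": [1, 0], "B": [1, 0], "C": [0, 0], "D": [0, 1], "E": [0, 1]},
            [1, 2],
        )
        records = transformations(reconstruct(tree, matrix, cat))
        keys = [(r.node_id, r.char_id) for r in records]
        assert keys == sorted(keys)

    def test_parsimony_never_overcounts_truth(self):
        config = SimConfig(
            n_taxa=10, seed=3, catalog=simple_catalog(n_chars=40, k=2),
            morph_rate=0.15,
        )
        tree = simulate_tree(config)
        matrix, truth = simulate_morphology(tree, config)
        result = reconstruct(tree, matrix, config.catalog)
        records = transformations(result)
        assert len(records) <= truth.total_changes()


class TestStemState:
    def test_whole_tree_gives_root_set(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog()
        matrix = matrix_from_rows(
            {"A": [0], "B": [1], "C": [0], "D": [0], "E": [0]}, [1]
        )
        result = reconstruct(tree, matrix, cat)
        root_id = result.node_id_of(result.tree.root)
        assert stem_state(result, set("ABCDE"), 1) == result.states[root_id][1]

    def test_cherry_with_identical_states(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog()
        matrix = matrix_from_rows(
            {"A": [1], "B": [1], "C": [0], "D": [0], "E": [0]}, [1]
        )
        result = reconstruct(tree, matrix, cat)
        assert stem_state(result, {"A", "B"}, 1) == frozenset({1})

    def test_non_monophyletic_set_names_intruders(self):
        tree = PhyloTree.from_newick(FIVE)
        cat = simple_catalog()
        matrix = matrix_from_rows({t: [0] for t in "ABCDE"}, [1])
        result = reconstruct(tree, matrix, cat)
        with pytest.raises(ASRError, match="B"):
            stem_state(result, {"A", "C"}, 1)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_true_state_recovery_improves_as_rate_drops(self, seed):
        rates = [1.5, 0.4, 0.02]
        hit_rates = []
        for rate in rates:
            config = SimConfig(
                n_taxa=14, seed=seed,
                catalog=simple_catalog(n_chars=60, k=2), morph_rate=rate,
            )
            tree = simulate_tree(config)
            matrix, truth = simulate_morphology(tree, config)
            result = reconstruct(tree, matrix, config.catalog)
            hits = total = 0
            for nid, node in result.node_ids.items():
                if node.is_leaf:
                    continue
                for cid in result.char_ids():
                    total += 1
                    if truth.node_states[nid][cid] in result.states[nid][cid]:
                        hits += 1
            hit_rates.append(hits / total)
        assert hit_rates[0] <= hit_rates[1] <= hit_rates[2]
        assert hit_rates[2] > 0.99
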