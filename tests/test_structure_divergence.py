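import itertools

import numpy as np
import pytest

from rlrkit.io_formats import parse_newick
from rlrkit.pairwise_align import Scoring, global_align
from rlrkit.structure_divergence import (
    EXONIZATION,
    GAIN_LOSS,
    INTRAEXONIC_INDEL,
    DivergenceCall,
    classify_mechanisms,
    compare_pair,
    extract_sibling_pairs,
    is_structurally_divergent,
    mechanism_census,
    pair_exon_homology,
)
from rlrkit.synthetic_data import gen_sibling_pair


def _random_topology(rng, labels):
    """Random binary tree by seeded sequential joining of subtrees."""
    nodes = [f"{x}:1" for x in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return nodes[0][: nodes[0].rfind(":")] + ";"


def _brute_force_cherries(tree):
    """Independent cherry enumeration: leaf pairs at patristic rank 1 parent."""
    out = set()
    for nd in tree.preorder_node_iter():
        kids = nd.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            out.add(frozenset(k.taxon.label for k in kids))
    return out


class TestSiblingPairs:
    def test_cherry_is_paralog_when_species_match(self):
        tree = parse_newick("((spA_1:1,spA_2:1):1,spB_1:2);")
        pairs = extract_sibling_pairs(tree, {"spA_1", "spA_2", "spB_1"})
        assert len(pairs) == 1
        assert pairs[0].relation == "paralog"
        assert {pairs[0].gene_a, pairs[0].gene_b} == {"spA_1", "spA_2"}

    def test_ortholog_relation_across_species(self):
        tree = parse_newick("((spA_1:1,spB_1:1):1,spC_1:2);")
        (pair,) = extract_sibling_pairs(tree, {"spA_1", "spB_1", "spC_1"})
        assert pair.relation == "ortholog"

    def test_caterpillar_has_single_cherry(self):
        tree = parse_newick("(((spA_a:1,spA_b:1):1,spA_c:1):1,spA_d:1);")
        pairs = extract_sibling_pairs(tree, {"spA_a", "spA_b", "spA_c", "spA_d"})
        assert len(pairs) == 1
        assert {pairs[0].gene_a, pairs[0].gene_b} == {"spA_a", "spA_b"}

    def test_empty_gene_set_gives_empty_list(self):
        tree = parse_newick("((spA_1:1,spA_2:1):1,spB_1:2);")
        assert extract_sibling_pairs(tree, set()) == []

    def test_missing_species_tag_is_error(self):
        tree = parse_newick("((nounderscorea:1,spA_2:1):1,spB_1:2);")
        with pytest.raises(ValueError, match="species tag"):
            extract_sibling_pairs(tree, {"nounderscorea", "spA_2"})

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(11)
        for rep in range(20):
            labels = [f"sp{i}_g" for i in range(10)]
            tree = parse_newick(_random_topology(rng, labels))
            got = {
                frozenset((p.gene_a, p.gene_b))
                for p in extract_sibling_pairs(tree, set(labels))
            }
            assert got == _brute_force_cherries(tree)


class TestExonHomology:
    def test_identical_genes_match_fully(self):
        gm_a, gm_b, _, _, _ = gen_sibling_pair("NONE", 0.0, seed=1)
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        assert len(corr.matched) == gm_a.n_exons
        assert corr.orphans_a == [] and corr.orphans_b == []
        assert all(fa == 1.0 and fb == 1.0 for _, _, fa, fb in corr.matched)

    def test_planted_extra_exon_becomes_orphan(self):
        gm_a, gm_b, _, _, truth = gen_sibling_pair("GAIN_LOSS", 0.05, seed=2)
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        orphans = corr.orphans_a if truth.carrier == "a" else corr.orphans_b
        assert len(orphans) == 1
        assert len(corr.matched) == 5  # ancestral exons still pair up

    def test_intron_gain_produces_split_candidate(self):
        gm_a, gm_b, _, _, truth = gen_sibling_pair("SPLIT", 0.05, seed=3)
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        splits = (
            corr.split_candidates_a if truth.carrier == "a" else corr.split_candidates_b
        )
        assert len(splits) == 1


class TestDivergenceRule:
    def test_identical_models_not_divergent(self):
        gm_a, gm_b, _, _, _ = gen_sibling_pair("NONE", 0.0, seed=4)
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        assert not is_structurally_divergent(corr, gm_a, gm_b)

    def test_same_count_different_length_is_divergent(self):
        gm_a, gm_b, _, _, _ = gen_sibling_pair("INTRAEXONIC_INDEL", 0.0, seed=5)
        assert gm_a.n_exons == gm_b.n_exons
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        assert is_structurally_divergent(corr, gm_a, gm_b)

    def test_different_exon_count_is_divergent(self):
        gm_a, gm_b, _, _, _ = gen_sibling_pair("SPLIT", 0.0, seed=6)
        aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                           Scoring.protein_default())
        corr = pair_exon_homology(gm_a, gm_b, aln)
        assert is_structurally_divergent(corr, gm_a, gm_b)


class TestMechanismClassification:
    @pytest.mark.parametrize(
        "mechanism,expected",
        [
            ("NONE", set()),
            ("GAIN_LOSS", {GAIN_LOSS}),
            ("EXONIZATION", {EXONIZATION}),
            ("INTRAEXONIC_INDEL", {INTRAEXONIC_INDEL}),
            ("SPLIT", {GAIN_LOSS}),
        ],
    )
    def test_planted_mechanism_recovered(self, mechanism, expected):
        for seed in range(3):
            gm_a, gm_b, wa, wb, truth = gen_sibling_pair(mechanism, 0.1, seed=seed)
            call = compare_pair(gm_a, gm_b, wa, wb)
            assert call.mechanisms == expected
            assert call.structurally_divergent == bool(expected) or mechanism == "NONE"

    def test_symmetry_under_pair_swap(self):
        for mech in ("GAIN_LOSS", "EXONIZATION", "INTRAEXONIC_INDEL"):
            gm_a, gm_b, wa, wb, _ = gen_sibling_pair(mech, 0.1, seed=7)
            fwd = compare_pair(gm_a, gm_b, wa, wb)
            rev = compare_pair(gm_b, gm_a, wb, wa)
            assert fwd.mechanisms == rev.mechanisms

    def test_no_divergence_soundness(self):
        """Identical inputs can never yield a mechanism."""
        for seed in range(5):
            gm_a, gm_b, wa, wb, _ = gen_sibling_pair("NONE", 0.0, seed=seed)
            call = compare_pair(gm_a, gm_b, wa, wb)
            assert call.mechanisms == set()
            assert not call.structurally_divergent

    def test_missing_window_with_orphan_is_error(self):
        gm_a, gm_b, wa, wb, truth = gen_sibling_pair("GAIN_LOSS", 0.05, seed=8)
        with pytest.raises(ValueError, match="no genomic window"):
            compare_pair(gm_a, gm_b, None, None)

    def test_exonization_identity_reflects_background_divergence(self):
        """Planted exonization aligns to the partner intron near (1-d)^2."""
        gm_a, gm_b, wa, wb, truth = gen_sibling_pair("EXONIZATION", 0.1, seed=9)
        call = compare_pair(gm_a, gm_b, wa, wb)
        ev = [e for e in call.evidence if e["mechanism"] == EXONIZATION]
        assert ev and ev[0]["intronic_identity"] >= 1 - 2 * 0.1 - 0.05


class TestCensus:
    def test_counts_with_overlapping_mechanisms(self):
        calls = [
            DivergenceCall(("a", "b"), True, {GAIN_LOSS}),
            DivergenceCall(("c", "d"), True, {GAIN_LOSS, EXONIZATION}),
            DivergenceCall(("e", "f"), True, {EXONIZATION}),
        ]
        census = mechanism_census(calls)
        assert census[GAIN_LOSS] == 2
        assert census[EXONIZATION] == 2
        assert census[INTRAEXONIC_INDEL] == 0

    def test_empty_input_all_zero(self):
        assert all(v == 0 for v in mechanism_census([]).values())

    def test_synthetic_census_equals_planted_multiset(self):
        mechs = ["EXONIZATION"] * 5 + ["GAIN_LOSS"] * 4 + ["INTRAEXONIC_INDEL"]
        calls = []
        for i, m in enumerate(mechs):
            gm_a, gm_b, wa, wb, _ = gen_sibling_pair(m, 0.1, seed=100 + i)
            calls.append(compare_pair(gm_a, gm_b, wa, wb))
        census = mechanism_census(calls)
        assert census == {EXONIZATION: 5, GAIN_LOSS: 4, INTRAEXONIC_INDEL: 1}
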