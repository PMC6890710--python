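"""Gene-tree rooting, subtree matching, and duplication tallying."""

import pytest

from ploidyscape.mapscan import (
    SpeciesTree,
    clade_from_newick,
    collapse_low_support,
    match_subtrees,
    matches,
    matches_with_duplication,
    root_gene_tree,
    tally_duplications,
)
from ploidyscape.synthdata import simulate_gene_trees


def tally_by_label(tallies):
    return {t.node_label: t for t in tallies}


# ---------------------------------------------------------------------------
# rooting


def test_rooting_is_idempotent_on_correctly_rooted_tree(species_tree):
    nwk = "(Physcomitrella|g0,(Selaginella|g0,(Amborella|g0,(Equisetum|g0,(Ceratopteris|g0,Azolla|g0)))));"
    rooted = root_gene_tree(nwk, "Physcomitrella")
    tallies = tally_duplications([rooted], species_tree)
    by = tally_by_label(tallies)
    assert by["Azolla+Ceratopteris"].n_matching_subtrees == 1
    assert by["Azolla+Ceratopteris"].n_duplicated == 0


def test_rooting_places_single_outgroup_tip_basally(species_tree):
    # written rooted elsewhere: outgroup buried inside
    nwk = "((Ceratopteris|g0,Azolla|g0),(Equisetum|g0,Physcomitrella|g0));"
    rooted = root_gene_tree(nwk, "Physcomitrella")
    assert rooted is not None
    top = rooted.children
    sides = [c.species_set() for c in top]
    assert frozenset({"Physcomitrella"}) in sides


def test_tree_without_outgroup_is_skipped():
    nwk = "((Ceratopteris|g0,Azolla|g0),Equisetum|g0);"
    assert root_gene_tree(nwk, "Physcomitrella") is None


# ---------------------------------------------------------------------------
# matching


def test_relabeled_species_tree_matches_each_internal_node(species_tree):
    gene = clade_from_newick(
        "(Physcomitrella|g0,(Selaginella|g0,(Amborella|g0,(Equisetum|g0,(Ceratopteris|g0,Azolla|g0)))));"
    )
    for node in species_tree.internal_nodes_shallowest_first():
        assert len(match_subtrees(gene, species_tree, node)) == 1


def test_topology_mismatch_is_rejected(species_tree):
    node = species_tree.node({"Ceratopteris", "Azolla"})
    wrong = clade_from_newick("((Ceratopteris|g0,Equisetum|g0),Azolla|g0);")
    assert match_subtrees(wrong, species_tree, node) == []
    assert not matches(wrong, node)


def test_same_species_duplicates_collapse_to_one_leaf(species_tree):
    node = species_tree.node({"Ceratopteris", "Azolla"})
    gene = clade_from_newick("((Ceratopteris|g0,Ceratopteris|g1),Azolla|g0);")
    assert matches(gene, node)


def test_duplicated_clade_is_detected_at_the_node(species_tree):
    node = species_tree.node({"Ceratopteris", "Azolla"})
    dup = clade_from_newick(
        "(((Ceratopteris|g0,Azolla|g0),(Ceratopteris|g1,Azolla|g1)),Equisetum|g0);"
    )
    inner = dup.children[0]
    assert matches_with_duplication(inner, node)
    assert not matches(inner, node)
    # the two inner (Cer,Azo) clades are the maximal matching subtrees
    assert len(match_subtrees(dup, species_tree, node)) == 2


def test_polytomies_never_match(species_tree):
    node = species_tree.node({"Ceratopteris", "Azolla", "Equisetum"})
    poly = clade_from_newick("(Ceratopteris|g0,Azolla|g0,Equisetum|g0);")
    assert not matches(poly, node)


def test_support_collapse_creates_polytomy():
    gene = clade_from_newick(
        "((Ceratopteris|g0,Azolla|g0)30,Equisetum|g0)90;"
    )
    collapsed = collapse_low_support(gene, 50)
    assert len(collapsed.children) == 3


# ---------------------------------------------------------------------------
# tallying


def test_exact_species_tree_copies_have_zero_proportions(species_tree):
    trees, _ = simulate_gene_trees(species_tree, 10, {}, seed=0)
    rooted = [root_gene_tree(n, "Physcomitrella") for n in trees]
    tallies = tally_duplications(rooted, species_tree)
    for t in tallies:
        assert t.n_matching_subtrees == 10
        assert t.n_duplicated == 0


def test_forced_duplication_gives_proportion_one(species_tree):
    trees, _ = simulate_gene_trees(
        species_tree, 10, {"Azolla+Ceratopteris": 1.0}, seed=1
    )
    rooted = [root_gene_tree(n, "Physcomitrella") for n in trees]
    by = tally_by_label(tally_duplications(rooted, species_tree))
    t = by["Azolla+Ceratopteris"]
    assert t.n_matching_subtrees == 10 and t.n_duplicated == 10
    assert t.proportion == 1.0


def test_numerator_equals_planted_count_exactly(species_tree):
    trees, truth = simulate_gene_trees(
        species_tree, 400, {"Azolla+Ceratopteris": 0.3}, seed=2
    )
    rooted = [root_gene_tree(n, "Physcomitrella") for n in trees]
    by = tally_by_label(tally_duplications(rooted, species_tree))
    planted = sum(
        c for evs in truth.tree_truth.values() for node, c in evs
        if node == "Azolla+Ceratopteris"
    )
    assert by["Azolla+Ceratopteris"].n_duplicated == planted


def test_gene_relabeling_within_species_changes_no_tally(species_tree):
    trees, _ = simulate_gene_trees(
        species_tree, 50, {"Azolla+Ceratopteris": 0.5}, seed=3
    )
    rooted = [root_gene_tree(n, "Physcomitrella") for n in trees]
    relabeled = [
        root_gene_tree(n.replace("|g0", "|x9").replace("|g1", "|y7"), "Physcomitrella")
        for n in trees
    ]
    t1 = [(t.n_matching_subtrees, t.n_duplicated) for t in tally_duplications(rooted, species_tree)]
    t2 = [(t.n_matching_subtrees, t.n_duplicated) for t in tally_duplications(relabeled, species_tree)]
    assert t1 == t2


def test_tree_without_clade_species_joins_no_tally(species_tree):
    base, _ = simulate_gene_trees(species_tree, 5, {}, seed=4)
    rooted = [root_gene_tree(n, "Physcomitrella") for n in base]
    before = tally_by_label(tally_duplications(rooted, species_tree))
    extra = root_gene_tree(
        "(Physcomitrella|g0,(Selaginella|g0,Amborella|g0));", "Physcomitrella"
    )
    after = tally_by_label(tally_duplications(rooted + [extra], species_tree))
    t = after["Azolla+Ceratopteris"]
    assert (t.n_matching_subtrees, t.n_duplicated) == (
        before["Azolla+Ceratopteris"].n_matching_subtrees,
        before["Azolla+Ceratopteris"].n_duplicated,
    )


def test_strict_flag_admits_only_full_species_coverage(species_tree):
    full, _ = simulate_gene_trees(species_tree, 4, {}, seed=5)
    rooted = [root_gene_tree(n, "Physcomitrella") for n in full]
    partial = root_gene_tree(
        "(Physcomitrella|g0,(Equisetum|g0,(Ceratopteris|g0,Azolla|g0)));",
        "Physcomitrella",
    )
    strict = tally_by_label(
        tally_duplications(rooted + [partial], species_tree, strict_all_species=True)
    )
    assert strict["Azolla+Ceratopteris"].n_matching_subtrees == 4


def test_unknown_dup_node_raises_with_name(species_tree):
    with pytest.raises(KeyError, match="Azolla\\+Physcomitrella"):
        simulate_gene_trees(species_tree, 1, {"Azolla+Physcomitrella": 0.5}, seed=0)
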