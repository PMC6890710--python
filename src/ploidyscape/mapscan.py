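"""MAPS-style gene-tree / species-tree duplication tallying.

Given rooted gene-family trees (tips labeled ``species|gene``) and a
known species tree, filter for gene-tree subtrees whose topology
matches the species tree pruned at a node, and tally per species-tree
node the proportion of such subtrees in which the node position holds
two sister copies of the matching clade — the signature of a gene
duplication shared by all descendant species, and in aggregate of an
ancient whole-genome duplication.

Matching rules (pinned by tests):

* a clade of one or more tips all from species s matches the pruned
  tree consisting of s alone (same-species duplicates are collapsed);
* an internal match requires a bifurcation whose two children match
  the two children of the pruned species tree (either order);
* the denominator for node N counts gene-tree nodes presenting N's
  parent context — one child matching N's sibling lineage, the other
  child either matching the pruned tree at N (no duplication) or
  carrying two sister sub-clades that each match it (duplication);
* polytomies (e.g. after support collapsing) never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

SEP = "|"


@dataclass
class Clade:
    """Lightweight rooted tree node; tips carry species (and gene) labels."""

    children: list["Clade"] = field(default_factory=list)
    species: str | None = None
    gene: str | None = None
    support: float | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Clade"]:
        if self.is_tip:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def species_set(self) -> frozenset[str]:
        return frozenset(t.species for t in self.tips())

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def to_newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_tip:
            return f"{self.species}{SEP}{self.gene}" if self.gene else self.species
        inner = ",".join(c._nwk() for c in self.children)
        sup = "" if self.support is None else format(self.support, "g")
        return f"({inner}){sup}"


def _from_dendropy(node: dendropy.Node, parse_species: bool) -> Clade:
    if node.is_leaf():
        label = node.taxon.label if node.taxon else (node.label or "")
        if parse_species and SEP in label:
            sp, gene = label.split(SEP, 1)
        else:
            sp, gene = label, None
        return Clade(species=sp, gene=gene)
    support = None
    if node.label:
        try:
            support = float(node.label)
        except ValueError:
            support = None
    return Clade(
        children=[_from_dendropy(c, parse_species) for c in node.child_nodes()],
        support=support,
    )


def clade_from_newick(newick: str, parse_species: bool = True) -> Clade:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    root = tree.seed_node
    # drop a degree-1 artificial root if present
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    return _from_dendropy(root, parse_species)


class SpeciesTree:
    """Rooted bifurcating species tree; internal nodes addressed by the
    frozenset of their descendant species."""

    def __init__(self, root: Clade):
        self.root = root
        self._by_species_set: dict[frozenset[str], Clade] = {}
        for node in root.preorder():
            if not node.is_tip:
                if len(node.children) != 2:
                    raise ValueError("species tree must be fully bifurcating")
                self._by_species_set[node.species_set()] = node
        tips = [t.species for t in root.tips()]
        if len(set(tips)) != len(tips):
            raise ValueError("species tree tip labels must be unique")
        self.species: frozenset[str] = frozenset(tips)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        return cls(clade_from_newick(newick, parse_species=False))

    def node(self, species: frozenset[str] | set[str]) -> Clade:
        key = frozenset(species)
        if key not in self._by_species_set:
            raise KeyError(f"no internal node with species set {sorted(key)}")
        return self._by_species_set[key]

    def internal_nodes_shallowest_first(self) -> list[Clade]:
        nodes = [n for n in self.root.preorder() if not n.is_tip]
        nodes.sort(key=lambda n: len(n.species_set()))
        return [n for n in nodes if n is not self.root]

    def parent_and_sibling(self, node: Clade) -> tuple[Clade, Clade]:
        for parent in self.root.preorder():
            if node in parent.children:
                sib = parent.children[0] if parent.children[1] is node else parent.children[1]
                return parent, sib
        raise ValueError("node not found below the root")

    def node_label(self, node: Clade) -> str:
        if node.is_tip:
            return node.species
        return "+".join(sorted(node.species_set()))


# ---------------------------------------------------------------------------
# rooting


def root_gene_tree(newick: str, outgroup_species: set[str] | str) -> Clade | None:
    """Root a gene tree on the smallest clade holding all outgroup tips.

    Returns None (skip semantics) when the tree has no outgroup tip.
    """
    if isinstance(outgroup_species, str):
        outgroup_species = {outgroup_species}
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    out_taxa = [
        leaf.taxon
        for leaf in tree.leaf_node_iter()
        if leaf.taxon and leaf.taxon.label.split(SEP, 1)[0] in outgroup_species
    ]
    if not out_taxa:
        return None
    if len(out_taxa) == len(tree.taxon_namespace):
        return None  # outgroup-only tree carries no ingroup signal
    if len(out_taxa) == 1:
        node = tree.find_node_for_taxon(out_taxa[0])
    else:
        node = tree.mrca(taxa=out_taxa)
        if node is tree.seed_node:
            # outgroup straddles the current root: root on the ingroup side
            in_taxa = [t for t in tree.taxon_namespace if t not in out_taxa]
            node = (
                tree.find_node_for_taxon(in_taxa[0])
                if len(in_taxa) == 1
                else tree.mrca(taxa=in_taxa)
            )
            if node is tree.seed_node:
                return clade_from_newick(
                    tree.as_string(schema="newick").strip(), parse_species=True
                )
    tree.reroot_at_edge(node.edge, update_bipartitions=False, suppress_unifurcations=True)
    return clade_from_newick(tree.as_string(schema="newick").strip(), parse_species=True)


# ---------------------------------------------------------------------------
# matching


def collapse_low_support(clade: Clade, threshold: float) -> Clade:
    """Collapse internal nodes with support below threshold to polytomies."""
    if clade.is_tip:
        return Clade(species=clade.species, gene=clade.gene)
    new_children: list[Clade] = []
    for c in clade.children:
        cc = collapse_low_support(c, threshold)
        if (
            not cc.is_tip
            and cc.support is not None
            and cc.support < threshold
        ):
            new_children.extend(cc.children)
        else:
            new_children.append(cc)
    return Clade(children=new_children, support=clade.support)


def matches(gene_clade: Clade, pruned: Clade) -> bool:
    """Does a gene-tree clade match a pruned species tree topologically?"""
    if pruned.is_tip:
        return all(t.species == pruned.species for t in gene_clade.tips())
    if len(gene_clade.children) != 2:
        return False
    g1, g2 = gene_clade.children
    s1, s2 = pruned.children
    return (matches(g1, s1) and matches(g2, s2)) or (
        matches(g1, s2) and matches(g2, s1)
    )


def matches_with_duplication(gene_clade: Clade, pruned: Clade) -> bool:
    """Clade = two sister sub-clades that each match (or recursively
    dup-match) the pruned tree: a duplication at the pruned tree's root."""
    if len(gene_clade.children) != 2:
        return False
    g1, g2 = gene_clade.children
    ok1 = matches(g1, pruned) or matches_with_duplication(g1, pruned)
    ok2 = matches(g2, pruned) or matches_with_duplication(g2, pruned)
    return ok1 and ok2


def match_subtrees(gene_tree: Clade, species_tree: SpeciesTree, node: Clade) -> list[Clade]:
    """Maximal gene-tree clades matching the species tree pruned at node."""
    if node.is_tip:
        raise ValueError("node must be internal in the species tree")
    hits: list[Clade] = []

    def walk(g: Clade, inside_match: bool) -> None:
        hit = matches(g, node)
        if hit and not inside_match:
            hits.append(g)
        for c in g.children:
            walk(c, inside_match or hit)

    walk(gene_tree, False)
    return hits


# ---------------------------------------------------------------------------
# tallying


@dataclass
class NodeTally:
    node_label: str
    species: frozenset[str]
    n_matching_subtrees: int = 0
    n_duplicated: int = 0

    @property
    def proportion(self) -> float | None:
        if self.n_matching_subtrees == 0:
            return None
        return self.n_duplicated / self.n_matching_subtrees


def tally_duplications(
    gene_trees: list[Clade],
    species_tree: SpeciesTree,
    collapse_support: float | None = None,
    strict_all_species: bool = False,
) -> list[NodeTally]:
    """Per species-tree internal node: available subtrees and the share
    containing a duplication at that node.

    A gene-tree node contributes to node N's denominator when one child
    matches N's sibling lineage and the other presents N's clade,
    either singly (no duplication) or as two matching sister copies
    (duplication, counted in the numerator).
    """
    tallies: list[NodeTally] = []
    contexts = []
    for node in species_tree.internal_nodes_shallowest_first():
        _, sibling = species_tree.parent_and_sibling(node)
        tally = NodeTally(
            node_label=species_tree.node_label(node),
            species=node.species_set(),
        )
        tallies.append(tally)
        contexts.append((node, sibling, tally))

    for tree in gene_trees:
        if collapse_support is not None:
            tree = collapse_low_support(tree, collapse_support)
        if strict_all_species and tree.species_set() != species_tree.species:
            continue
        for g in tree.preorder():
            if len(g.children) != 2:
                continue
            g1, g2 = g.children
            for node, sibling, tally in contexts:
                for a, b in ((g1, g2), (g2, g1)):
                    if not matches(b, sibling):
                        continue
                    if matches(a, node):
                        tally.n_matching_subtrees += 1
                        break
                    if matches_with_duplication(a, node):
                        tally.n_matching_subtrees += 1
                        tally.n_duplicated += 1
                        break
    return tallies


def tallies_to_rows(tallies: list[NodeTally]) -> list[dict]:
    rows = []
    for t in tallies:
        rows.append(
            {
                "node": t.node_label,
                "n_matching": t.n_matching_subtrees,
                "n_dup": t.n_duplicated,
                "proportion": "." if t.proportion is None else round(t.proportion, 4),
            }
        )
    return rows
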