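"""Synthetic gene trees following a species tree, with planted
whole-clade duplications at chosen species-tree nodes."""

from __future__ import annotations

import numpy as np

from ..mapscan import Clade, SpeciesTree
from .truth import TruthTable


def _normalize_dup_probs(
    species_tree: SpeciesTree, dup_probs: dict
) -> dict[int, tuple[str, float]]:
    """Map node -> (label, prob), validating that each key names an
    internal species-tree node."""
    out: dict[int, tuple[str, float]] = {}
    for key, prob in dup_probs.items():
        if isinstance(key, str):
            species = frozenset(key.split("+"))
        else:
            species = frozenset(key)
        try:
            node = species_tree.node(species)
        except KeyError as exc:
            raise KeyError(
                f"dup_probs key {key!r} is not an internal node of the species tree"
            ) from exc
        out[id(node)] = (species_tree.node_label(node), float(prob))
    return out


def simulate_gene_trees(
    species_tree: SpeciesTree,
    n_trees: int,
    dup_probs: dict,
    seed: int,
) -> tuple[list[str], TruthTable]:
    """Newick gene trees mirroring the species tree topology.

    At each flagged node, with its probability, the entire descendant
    clade is duplicated (both copies retained in all descendant
    species).  The decision is made independently for every occurrence
    of the node, so a clade nested under an already-duplicated ancestor
    may duplicate again in either copy.  Tips are labeled
    ``species|gene`` with genes numbered per species within each tree.
    """
    probs = _normalize_dup_probs(species_tree, dup_probs)
    rng = np.random.default_rng(seed)
    trees: list[str] = []
    truth = TruthTable()
    for t in range(n_trees):
        counters: dict[str, int] = {}
        events: dict[str, int] = {}

        def build(sp_node: Clade) -> Clade:
            label_prob = probs.get(id(sp_node))
            if label_prob is not None and rng.random() < label_prob[1]:
                events[label_prob[0]] = events.get(label_prob[0], 0) + 1
                return Clade(children=[build_below(sp_node), build_below(sp_node)])
            return build_below(sp_node)

        def build_below(sp_node: Clade) -> Clade:
            if sp_node.is_tip:
                n = counters.get(sp_node.species, 0)
                counters[sp_node.species] = n + 1
                return Clade(species=sp_node.species, gene=f"g{n}")
            return Clade(children=[build(c) for c in sp_node.children])

        gene_tree = build(species_tree.root)
        tree_id = f"tree{t:05d}"
        trees.append(gene_tree.to_newick())
        truth.tree_truth[tree_id] = sorted(events.items())
    return trees, truth
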