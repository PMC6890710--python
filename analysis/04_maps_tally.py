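#!/usr/bin/env python
"""Gene-duplication mapping onto the species tree.

Roots each gene tree on the outgroup, filters for subtrees matching
the species tree, and tallies per node the share of subtrees with a
duplication shared by all descendant species.  Reads results/synth/,
writes results/maps/maps_tally.tsv.
"""

import argparse
from pathlib import Path

from ploidyscape import io
from ploidyscape.config import write_provenance
from ploidyscape.mapscan import SpeciesTree
from ploidyscape.pipeline import run_maps


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--synth", type=Path, default=Path("results/synth"))
    ap.add_argument("--out", type=Path, default=Path("results/maps"))
    args = ap.parse_args()
    newicks = io.read_newick_list(args.synth / "gene_trees.nwk")
    sp = SpeciesTree.from_newick(io.read_newick(args.synth / "species_tree.nwk"))
    tallies, n_skipped = run_maps(newicks, sp, out_dir=args.out)
    write_provenance(args.out, "maps", None, {"synth": str(args.synth)})
    print(f"{len(newicks)} gene trees ({n_skipped} without outgroup skipped)")
    for t in tallies:
        prop = "NA" if t.proportion is None else f"{t.proportion:.1%}"
        print(f"  {t.node_label}: {t.n_duplicated}/{t.n_matching_subtrees} = {prop}")


if __name__ == "__main__":
    main()
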