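"""Stage drivers gluing the analysis modules into one pipeline.

Each function runs one stage on in-memory objects and (optionally)
writes the stage's standard output files; the CLI, the numbered
analysis scripts, and the acceptance checks all call these.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import DEFAULT_SPECIES_TREE, io, ksdist, sizer as sizer_mod
from .ltr import (
    LTRParams,
    build_exemplars,
    classify_age_class,
    date_insertions,
    filter_candidates,
    find_ltr_candidates,
    mask_genome,
    summarize_repeats,
    summary_to_rows,
)
from .mapscan import SpeciesTree, root_gene_tree, tally_duplications, tallies_to_rows
from .synthdata import SimConfig, simulate_gene_families, simulate_gene_trees, simulate_ltr_genome


def default_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_SPECIES_TREE)


def default_dup_probs() -> dict[str, float]:
    """Planted duplication probabilities: the study's observed subtree
    proportions at the two fern nodes."""
    return {
        "Azolla+Ceratopteris": 0.34,
        "Azolla+Ceratopteris+Equisetum": 0.19,
    }


def run_simulate(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate all three synthetic substrates plus truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coding, proteins, fam_truth = simulate_gene_families(cfg)
    io.write_fasta(coding, out / "coding.fasta")
    io.write_fasta(proteins, out / "proteins.fasta")
    io.write_tsv(
        fam_truth.paralog_rows(),
        out / "truth_paralogs.tsv",
        ["gene_a", "gene_b", "true_ks", "origin"],
    )
    sp = default_species_tree()
    dup_probs = cfg.dup_probs or default_dup_probs()
    trees, tree_truth = simulate_gene_trees(sp, cfg.n_trees, dup_probs, cfg.seed + 17)
    (out / "gene_trees.nwk").write_text("\n".join(trees) + "\n", encoding="utf-8")
    io.write_newick(DEFAULT_SPECIES_TREE, out / "species_tree.nwk")
    io.write_tsv(tree_truth.tree_rows(), out / "truth_trees.tsv", ["tree", "node", "n_dup"])
    genome, elem_truth = simulate_ltr_genome(cfg)
    io.write_fasta(genome, out / "genome.fasta")
    io.write_gff3(elem_truth.element_gff_rows(), out / "truth_elements.gff3")
    return {name: out / name for name in (
        "coding.fasta", "proteins.fasta", "gene_trees.nwk",
        "species_tree.nwk", "genome.fasta", "truth_elements.gff3",
    )}


@dataclass
class KsResult:
    pairs: list
    histogram: ksdist.KsHistogram
    retained: list
    ks_values: np.ndarray


def run_ks(
    coding: dict[str, str],
    proteins: dict[str, str],
    min_identity: float = 40.0,
    min_aln_len: int = 100,
    out_dir: str | Path | None = None,
) -> KsResult:
    """Pair discovery -> codon alignment -> Ks -> filtered histogram."""
    ksdist.check_id_correspondence(proteins, coding)
    pair_ids = ksdist.find_paralog_pairs(proteins, min_identity, min_aln_len)
    pairs = [
        ksdist.estimate_pair_ks(a, b, coding, proteins) for a, b in pair_ids
    ]
    hist, retained = ksdist.build_ks_table(pairs)
    ks_values = np.array([p.Ks for p in retained], dtype=float)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tsv(
            ksdist.pairs_to_rows(pairs),
            out / "ks_pairs.tsv",
            ["gene_a", "gene_b", "n_codons", "S", "N", "Sd", "Nd", "Ks", "Ka", "saturated"],
        )
        edges = hist.bin_edges
        io.write_tsv(
            [
                {
                    "bin_start": round(float(edges[i]), 3),
                    "bin_end": round(float(edges[i + 1]), 3),
                    "count": int(c),
                }
                for i, c in enumerate(hist.counts)
            ],
            out / "ks_histogram.tsv",
            ["bin_start", "bin_end", "count"],
        )
    return KsResult(pairs, hist, retained, ks_values)


@dataclass
class SizerResult:
    map: sizer_mod.SiZerMap
    peaks: list
    values: np.ndarray


def run_sizer(
    ks_values: np.ndarray,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> SizerResult:
    x_grid, h_grid = sizer_mod.default_grids(ks_values)
    smap = sizer_mod.sizer_map(ks_values, x_grid, h_grid, alpha=alpha)
    peaks = sizer_mod.call_peaks(smap, ks_values)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tsv(sizer_mod.map_to_rows(smap), out / "sizer_map.tsv", ["x", "h", "state", "ess"])
        io.write_tsv(
            [
                {
                    "location": round(p.location, 4),
                    "bandwidth_support": round(p.bandwidth_support, 3),
                    "flank_lo": round(p.flank[0], 4),
                    "flank_hi": round(p.flank[1], 4),
                }
                for p in peaks
            ],
            out / "sizer_peaks.tsv",
            ["location", "bandwidth_support", "flank_lo", "flank_hi"],
        )
    return SizerResult(smap, peaks, ks_values)


def run_maps(
    gene_tree_newicks: list[str],
    species_tree: SpeciesTree,
    outgroup: str = "Physcomitrella",
    collapse_support: float | None = None,
    strict_all_species: bool = False,
    out_dir: str | Path | None = None,
):
    rooted = []
    n_skipped = 0
    for nwk in gene_tree_newicks:
        clade = root_gene_tree(nwk, outgroup)
        if clade is None:
            n_skipped += 1
            continue
        rooted.append(clade)
    tallies = tally_duplications(
        rooted, species_tree, collapse_support=collapse_support,
        strict_all_species=strict_all_species,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = tallies_to_rows(tallies)
        io.write_tsv(rows, out / "maps_tally.tsv", ["node", "n_matching", "n_dup", "proportion"])
    return tallies, n_skipped


@dataclass
class LTRResult:
    elements: list
    rejected: list
    recent: list
    ancient: list
    recent_library: object
    ages: list
    masked: dict[str, str]
    annotation: list[dict]
    summary: list


def run_ltr(
    genome: dict[str, str],
    params: LTRParams | None = None,
    out_dir: str | Path | None = None,
) -> LTRResult:
    """Full repeat-landscape stage: permissive structural scan, the
    three false-positive filters, recent/ancient classification with
    exemplar masking-exclusion, JC dating, soft-masking, summary."""
    params = params or LTRParams()
    candidates = find_ltr_candidates(genome, params.relaxed_for_ancient())
    kept, rejected = filter_candidates(candidates, genome)
    recent, ancient, recent_lib = classify_age_class(kept, genome, params)
    ages = date_insertions(recent, genome)
    combined = build_exemplars(recent + ancient, genome, label="all")
    masked, annotation = mask_genome(genome, combined)
    genome_len = sum(len(s) for s in genome.values())
    summary = summarize_repeats(annotation, genome_len)
    result = LTRResult(
        elements=recent + ancient,
        rejected=rejected,
        recent=recent,
        ancient=ancient,
        recent_library=recent_lib,
        ages=ages,
        masked=masked,
        annotation=annotation,
        summary=summary,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_gff3(io.elements_to_gff(result.elements), out / "ltr_elements.gff3")
        io.write_fasta(
            {ex.exemplar_id: ex.sequence for ex in combined.exemplars},
            out / "ltr_exemplars.fasta",
        )
        io.write_fasta(masked, out / "genome_softmasked.fasta")
        io.write_tsv(
            [
                {
                    "element": a.element_id,
                    "p": round(a.p, 6),
                    "d": "." if a.d is None else round(a.d, 6),
                    "age_years": "." if a.T is None else round(a.T, 1),
                    "n_sites": a.n_sites,
                    "saturated": int(a.saturated),
                }
                for a in ages
            ],
            out / "ltr_ages.tsv",
            ["element", "p", "d", "age_years", "n_sites", "saturated"],
        )
        io.write_tsv(
            summary_to_rows(summary),
            out / "repeat_summary.tsv",
            ["class", "element_count", "length_bp", "pct_genome", "mean_length"],
        )
    return result
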