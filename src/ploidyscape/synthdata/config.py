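"""Simulation configuration and its invariants."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generators.

    Gene-family block
    -----------------
    n_families / background_dup_rate (expected small-scale duplicates
    per family) / wgd_ks (synonymous divergence of WGD pairs, subs per
    synonymous site) / wgd_retention (probability a gene keeps its WGD
    duplicate) / ka_ks_ratio / gene_len_codons / marker_frac (share of
    frozen zero-synonymous-site codons providing protein identity
    signal).

    LTR-genome block
    ----------------
    genome_len (bp), n_elements, ltr_len_range and internal_len_range
    (bp), age_range (years), subst_rate (substitutions/site/year;
    default the neutral plant rate 6.5e-9), tsd_len (bp), nest_prob,
    gap_prob (probability an element body is corrupted by a >50-N
    run), decoy_count (tandem-duplication decoys with alignable
    flanks), n_element_families (independent ancestral element
    families), gc_content (background base composition; default 0.38).
    """

    seed: int = 0
    # gene families
    n_families: int = 500
    background_dup_rate: float = 0.5
    wgd_ks: float = 1.1
    wgd_retention: float = 0.3
    ka_ks_ratio: float = 0.15
    gene_len_codons: int = 300
    marker_frac: float = 0.25
    background_ks_range: tuple[float, float] = (0.05, 2.5)
    # LTR genome
    genome_len: int = 1_000_000
    n_elements: int = 50
    ltr_len_range: tuple[int, int] = (800, 1200)
    internal_len_range: tuple[int, int] = (2000, 8000)
    age_range: tuple[float, float] = (0.0, 7.0e6)
    subst_rate: float = 6.5e-9
    tsd_len: int = 5
    nest_prob: float = 0.1
    gap_prob: float = 0.05
    decoy_count: int = 5
    n_element_families: int = 3
    gc_content: float = 0.38
    # gene trees
    n_trees: int = 2000
    dup_probs: dict = field(default_factory=dict)

    MIN_LTR_DIST = 1500
    MAX_LTR_DIST = 25000

    def validate(self) -> None:
        for name in ("wgd_retention", "nest_prob", "gap_prob", "marker_frac", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.ltr_len_range
        if not (100 <= lo <= hi <= 6000):
            raise ValueError("ltr_len_range must lie within [100, 6000]")
        ilo, ihi = self.internal_len_range
        if ilo > ihi or ilo < 0:
            raise ValueError("invalid internal_len_range")
        if lo + ilo < self.MIN_LTR_DIST or hi + ihi > self.MAX_LTR_DIST:
            raise ValueError(
                "LTR-start spacing (ltr_len + internal_len) must stay within "
                f"[{self.MIN_LTR_DIST}, {self.MAX_LTR_DIST}]"
            )
        if self.age_range[0] < 0 or self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age_range")
        if self.subst_rate <= 0:
            raise ValueError("subst_rate must be positive")
        if self.tsd_len < 1:
            raise ValueError("tsd_len must be >= 1")
        if self.background_ks_range[0] <= 0 or (
            self.background_ks_range[0] > self.background_ks_range[1]
        ):
            raise ValueError("invalid background_ks_range")
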