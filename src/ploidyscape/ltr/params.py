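"""Parameter set and domain types for structural LTR-RT annotation."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class LTRParams:
    """Structural screen parameters.

    Defaults follow the LTRharvest-style protocol: LTR length window
    100-6000 bp, LTR-start distance window 1500-25000 bp, 5-bp
    target-site duplication, TG...CA termini searched within
    ``vicinity`` bp of the alignment boundaries, and a 90% LTR-pair
    identity floor for the recent class; the ancient class is
    collected at 75-90% identity without the motif requirement.
    ``seed_k`` and ``band`` are implementation constants of the
    seed-and-extend scan.
    """

    min_ltr_len: int = 100
    max_ltr_len: int = 6000
    min_ltr_dist: int = 1500
    max_ltr_dist: int = 25000
    tsd_len: int = 5
    motif: str | None = "tgca"
    min_similarity: float = 90.0
    vicinity: int = 10
    ancient_min_similarity: float = 75.0
    ancient_max_similarity: float = 90.0
    seed_k: int = 20
    band: int = 30
    require_motif: bool = True
    require_tsd: bool = True

    def validate(self) -> None:
        if not (0 < self.min_ltr_len <= self.max_ltr_len):
            raise ValueError("invalid LTR length window")
        if not (0 < self.min_ltr_dist <= self.max_ltr_dist):
            raise ValueError("invalid LTR distance window")
        for s in (self.min_similarity, self.ancient_min_similarity, self.ancient_max_similarity):
            if not 0 < s <= 100:
                raise ValueError("similarities must be in (0, 100]")

    def relaxed_for_ancient(self) -> "LTRParams":
        """Copy with the identity floor at the ancient threshold and no
        motif requirement — the single permissive scan the recent/
        ancient classifier is run on."""
        import dataclasses

        return dataclasses.replace(
            self,
            min_similarity=self.ancient_min_similarity,
            require_motif=False,
        )


@dataclass
class LTRElement:
    """One candidate/accepted paired-LTR element (0-based half-open
    coordinates on the forward strand)."""

    element_id: str
    contig: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    tsd: str = ""
    motif_ok: bool = False
    ltr_identity: float = 0.0
    age_class: str = ""                       # "", "recent" or "ancient"
    flags: set = field(default_factory=set)   # {"gappy","alignable_flanks","nested"}
    excised: tuple[int, int] | None = None    # nested span removed from the outer
    age_years: float | None = None
    age_saturated: bool = False
    superfamily: str = "LTR/unknown"

    @property
    def start(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]

    @property
    def internal(self) -> tuple[int, int]:
        return (self.ltr5[1], self.ltr3[0])

    @property
    def ltr_len(self) -> int:
        return self.ltr5[1] - self.ltr5[0]


@dataclass
class InsertionAge:
    """Jukes-Cantor LTR-pair divergence and the implied insertion age."""

    element_id: str
    p: float                 # mismatch proportion over aligned sites
    d: float | None          # JC distance, None when saturated
    mu: float                # substitutions / site / year
    T: float | None          # years since insertion = d / (2 mu)
    n_sites: int
    saturated: bool = False
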