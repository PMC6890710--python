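"""Nucleotide alignment helpers for the LTR modules.

Global (Needleman-Wunsch, affine-gap) alignment backs the LTR-pair
identity and dating computations; identity is always matches divided
by aligned residue columns, excluding gap columns and columns with an
N in either sequence.
"""

from __future__ import annotations

from Bio import Align

_NUC = None
_LOCAL = None


def _global_aligner() -> Align.PairwiseAligner:
    global _NUC
    if _NUC is None:
        a = Align.PairwiseAligner()
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -5
        a.extend_gap_score = -2
        a.mode = "global"
        _NUC = a
    return _NUC


def _local_aligner() -> Align.PairwiseAligner:
    global _LOCAL
    if _LOCAL is None:
        a = Align.PairwiseAligner()
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -5
        a.extend_gap_score = -2
        a.mode = "local"
        _LOCAL = a
    return _LOCAL


def _identity_of(aln) -> tuple[float, int, int]:
    """(identity fraction, matches, scored columns) over residue-residue
    non-N columns of a Bio.Align alignment."""
    s1, s2 = str(aln[0]).upper(), str(aln[1]).upper()
    matches = cols = 0
    for x, y in zip(s1, s2):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        cols += 1
        if x == y:
            matches += 1
    return (matches / cols if cols else 0.0), matches, cols


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and scored-column count of the global alignment."""
    if not a or not b:
        return 0.0, 0
    aln = _global_aligner().align(a.upper(), b.upper())[0]
    ident, _, cols = _identity_of(aln)
    return ident * 100.0, cols


_FLANK = None


def flank_identity(a: str, b: str) -> float:
    """Percent identity for flank-window comparison, with stiff gap
    penalties (open -10, extend -6).

    Tandem-duplication flanks are near-positionally identical and need
    no gaps, while permissive gap scores let two *random* 50-mers
    shuffle up to ~60% identity — enough to cross the alignable-flank
    threshold and disqualify genuine elements.
    """
    global _FLANK
    if _FLANK is None:
        _FLANK = Align.PairwiseAligner()
        _FLANK.match_score = 1
        _FLANK.mismatch_score = -1
        _FLANK.open_gap_score = -10
        _FLANK.extend_gap_score = -6
        _FLANK.mode = "global"
    if not a or not b:
        return 0.0
    aln = _FLANK.align(a.upper(), b.upper())[0]
    ident, _, _ = _identity_of(aln)
    return ident * 100.0


def global_mismatch_stats(a: str, b: str) -> tuple[int, int]:
    """(mismatches, scored columns) of the global alignment, excluding
    gap and N columns — the inputs to JC dating."""
    aln = _global_aligner().align(a.upper(), b.upper())[0]
    _, matches, cols = _identity_of(aln)
    return cols - matches, cols


def local_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """(percent identity, coverage of the shorter sequence) of the best
    local alignment — the exemplar-clustering comparison."""
    if not a or not b:
        return 0.0, 0.0
    aln = _local_aligner().align(a.upper(), b.upper())[0]
    ident, _, cols = _identity_of(aln)
    shorter = min(len(a), len(b))
    return ident * 100.0, 100.0 * cols / shorter if shorter else 0.0
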