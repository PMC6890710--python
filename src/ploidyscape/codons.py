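"""Nei-Gojobori (1986) codon machinery.

Synonymous/nonsynonymous site fractions per codon and path-averaged
difference counts per codon pair, under the standard genetic code.
These are the primitives behind the Ks estimates used for paralog-age
distributions: every quantity here is defined by exhaustive enumeration
of single-nucleotide mutants and of mutational paths, so results are
exact rational averages (no stochastic component).

Conventions
-----------
* Sites: for codon position i, ``s_i`` is the fraction of non-stop
  single-nucleotide mutants at that position that are synonymous;
  ``n_i = 1 - s_i``.  A codon's (s, n) sums to 3 exactly (stop mutants
  are excluded from the denominator, i.e. rescaled per position).
* Differences: for a codon pair differing at m positions, all m!
  orderings of the changes are enumerated; orderings passing through a
  stop codon are discarded; each surviving path classifies every step
  as synonymous or nonsynonymous, and (Sd, Nd) is the average over
  surviving paths.  If every ordering passes through a stop, the pair
  is uncountable and the caller should drop that codon column.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

_BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _mutants(codon: str, pos: int):
    for b in _BASES:
        if b != codon[pos]:
            yield codon[:pos] + b + codon[pos + 1 :]


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions (s, n) of one codon.

    Raises ``ValueError`` for stop codons or non-ACGT input.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for mut in _mutants(codon, pos):
            if mut in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TO_AA[mut] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Path-averaged (Sd, Nd) between two sense codons.

    Returns ``None`` when every mutational ordering passes through a
    stop codon (the column cannot be scored).  Symmetric in its
    arguments: every path a->b has a reversed path b->a with the same
    step classifications.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if blocked:
            continue
        n_paths += 1
        for c1, c2 in steps:
            if CODON_TO_AA[c1] == CODON_TO_AA[c2]:
                syn_total += 1
            else:
                non_total += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, non_total / n_paths


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon; '*' for a stop."""
    c = codon.upper()
    if c in STOP_CODONS:
        return "*"
    return CODON_TO_AA[c]
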