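"""Synthetic gene families with a planted WGD burst.

Design: substitution-count-driven codon evolution on a restricted
codon alphabet, so the planted Ks is exactly what the NG86+JC
estimator targets.

* Non-marker codons are drawn from the six "pure fourfold" families
  {GCN, GGN, GTN, ACN, CCN, TCN} (Ala, Gly, Val, Thr, Pro, Ser): their
  only synonymous single-nucleotide mutants are at the third position,
  which is fourfold degenerate, so each contributes exactly one
  synonymous site.  Synonymous evolution is a four-state Jukes-Cantor
  process on third positions (a Poisson number of events with mean
  Ks x S, multiple hits allowed), making NG86+JC unbiased for the
  planted divergence.
* Nonsynonymous evolution moves the first-two-base prefix along
  single-nucleotide edges *within* the six-family set, so it can never
  create a stop, never changes a codon's synonymous-site count, and is
  always nonsynonymous.  Realized Ka is therefore only approximately
  ka_ks_ratio x Ks; Ks, the recovery target, is exact.
* Marker codons (ATG/TGG: Met/Trp, the two zero-synonymous-site
  codons) are frozen, giving related proteins a conserved identity
  backbone and unrelated proteins a ~12% background identity, so the
  40%-identity pairing gate separates families cleanly.
"""

from __future__ import annotations

import numpy as np

from ..codons import translate_codon
from .config import SimConfig
from .truth import TruthTable

# prefixes of the pure fourfold codon families and their single-nt
# in-set neighbour prefixes
FAMILY_PREFIXES = ("GC", "GG", "GT", "AC", "CC", "TC")
_NEIGHBORS = {
    "GC": ("AC", "CC", "TC", "GG", "GT"),
    "AC": ("GC", "CC", "TC"),
    "CC": ("GC", "AC", "TC"),
    "TC": ("GC", "AC", "CC"),
    "GG": ("GC", "GT"),
    "GT": ("GC", "GG"),
}
MARKERS = ("ATG", "TGG")
_BASES = "ACGT"


def _ancestral_gene(rng: np.random.Generator, n_codons: int, marker_frac: float):
    """(prefix index array, third-base array, marker mask) of one gene.

    Markers are encoded with prefix index -1 and third base holding the
    marker choice (0 -> ATG, 1 -> TGG).
    """
    marker = rng.random(n_codons) < marker_frac
    prefix = rng.integers(0, len(FAMILY_PREFIXES), n_codons)
    third = rng.integers(0, 4, n_codons)
    prefix[marker] = -1
    third[marker] = rng.integers(0, 2, int(marker.sum()))
    return prefix, third, marker


def _to_sequences(prefix, third, marker) -> tuple[str, str]:
    """(coding DNA, protein) from the encoded representation."""
    codons = []
    for p, t, m in zip(prefix, third, marker):
        if m:
            codons.append(MARKERS[t])
        else:
            codons.append(FAMILY_PREFIXES[p] + _BASES[t])
    cds = "".join(codons)
    prot = "".join(translate_codon(c) for c in codons)
    return cds, prot


def _evolve(rng: np.random.Generator, prefix, third, marker, ks: float, ka_ks: float):
    """Copy the encoded gene and apply planted divergence ``ks``.

    Synonymous: Poisson(ks x S) JC events on third positions of
    non-marker codons.  Nonsynonymous: Poisson(ka_ks x ks x N) in-set
    prefix moves, N = 2 x S (two nonsynonymous sites per non-marker
    codon).
    """
    prefix = prefix.copy()
    third = third.copy()
    sites = np.flatnonzero(~marker)
    s_count = sites.size
    if s_count == 0:
        return prefix, third
    n_syn = rng.poisson(ks * s_count)
    for idx in rng.choice(sites, size=n_syn, replace=True) if n_syn else []:
        cur = third[idx]
        third[idx] = (cur + 1 + rng.integers(0, 3)) % 4
    n_non = rng.poisson(ka_ks * ks * 2 * s_count)
    for idx in rng.choice(sites, size=n_non, replace=True) if n_non else []:
        cur = FAMILY_PREFIXES[prefix[idx]]
        nbrs = _NEIGHBORS[cur]
        prefix[idx] = FAMILY_PREFIXES.index(nbrs[rng.integers(0, len(nbrs))])
    return prefix, third


def simulate_gene_families(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], TruthTable]:
    """Generate coding and protein FASTA records plus the truth table.

    Each family holds a base gene; with probability ``wgd_retention`` a
    WGD duplicate at divergence ``wgd_ks``; and a Poisson
    (``background_dup_rate``) number of small-scale duplicates at
    divergences uniform over ``background_ks_range``.  Internal stop
    codons cannot arise by construction, but generated sequences are
    checked anyway (defense against future edits).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    coding: dict[str, str] = {}
    proteins: dict[str, str] = {}
    truth = TruthTable()
    for fam in range(config.n_families):
        prefix, third, marker = _ancestral_gene(
            rng, config.gene_len_codons, config.marker_frac
        )
        base_id = f"fam{fam:05d}_g0"
        members = [(base_id, prefix, third)]
        if rng.random() < config.wgd_retention:
            p2, t2 = _evolve(rng, prefix, third, marker, config.wgd_ks, config.ka_ks_ratio)
            gid = f"fam{fam:05d}_gw"
            members.append((gid, p2, t2))
            truth.paralog_truth[(base_id, gid)] = (config.wgd_ks, "wgd")
        n_bg = rng.poisson(config.background_dup_rate)
        lo, hi = config.background_ks_range
        for k in range(n_bg):
            u = float(rng.uniform(lo, hi))
            p2, t2 = _evolve(rng, prefix, third, marker, u, config.ka_ks_ratio)
            gid = f"fam{fam:05d}_gb{k}"
            members.append((gid, p2, t2))
            truth.paralog_truth[(base_id, gid)] = (u, "background")
        for gid, p, t in members:
            cds, prot = _to_sequences(p, t, marker)
            if "*" in prot:
                raise AssertionError(f"internal stop generated in {gid}")
            coding[gid] = cds
            proteins[gid] = prot
    return coding, proteins, truth
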