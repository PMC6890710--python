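"""Paralog discovery and Ks (synonymous-distance) estimation.

Pipeline: find within-genome paralog pairs by protein similarity,
back-translate the protein alignment to a codon alignment, estimate
Ks/Ka with NG86 site counting plus Jukes-Cantor multiple-hit
correction, and bin the retained pairs into the paralog-age histogram
(0.05-wide Ks bins over [0.1, 2.1] by default).

The Ks estimator is deliberately the closed-form NG86+JC one: every
intermediate (site fractions, path-averaged difference counts) is
verifiable by brute-force enumeration, so planted-parameter recovery
tests have an unambiguous target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import is_stop, ng86_differences, ng86_sites

KS_BIN_WIDTH = 0.05
KS_MIN_DEFAULT = 0.1
KS_MAX_DEFAULT = 2.1
SATURATION_P = 0.75


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CodonAlignment:
    """Aligned codon columns of a paralog pair (gaps/ambiguity removed)."""

    pair_id: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences differ in length")
        if self.n_codons < 1:
            raise ValueError("empty codon alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class ParalogPair:
    """NG86 statistics and JC-corrected distances for one gene pair."""

    gene_a: str
    gene_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None = None
    pN: float | None = None
    Ks: float | None = None
    Ka: float | None = None
    saturated: bool = False


@dataclass
class KsHistogram:
    bin_width: float
    ks_min: float
    ks_max: float
    counts: np.ndarray
    n_pairs: int

    @property
    def bin_edges(self) -> np.ndarray:
        n = len(self.counts)
        return self.ks_min + self.bin_width * np.arange(n + 1)

    def mode_midpoint(self) -> float:
        """Midpoint of the fullest bin (leftmost on ties)."""
        i = int(np.argmax(self.counts))
        return self.ks_min + (i + 0.5) * self.bin_width


# ---------------------------------------------------------------------------
# paralog pair discovery


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    """Protein aligner.

    The local (pair-discovery) aligner uses identity scoring (match
    +2, mismatch -1, affine gaps -8/-2): the acceptance gate is percent
    identity, so the search optimizes the quantity being thresholded,
    and unrelated sequences cannot sustain a long high-identity local
    alignment by exploiting mild substitution-matrix off-diagonals.
    The global (back-translation) aligner uses BLOSUM62, the standard
    choice for aligning established homologs end to end.
    """
    aligner = Align.PairwiseAligner()
    if mode == "local":
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -8
        aligner.extend_gap_score = -2
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    aligner.mode = mode
    return aligner


def alignment_identity(alignment) -> tuple[float, int]:
    """(fractional identity, aligned-column count) over residue-residue
    columns of a Bio.Align alignment (gap columns excluded)."""
    a, b = alignment[0], alignment[1]
    matches = 0
    cols = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    return (matches / cols if cols else 0.0), cols


def _kmer_candidates(
    ids: list[str],
    seqs: list[str],
    k: int = 5,
    diag_bucket: int = 16,
    min_hits: int = 4,
) -> set[tuple[int, int]]:
    """Candidate pairs by shared-k-mer count per diagonal bucket.

    A FASTA-style seed stage: each shared k-mer occurrence pair votes
    for (gene_i, gene_j, diagonal//bucket); pairs with >= min_hits
    votes in some bucket are candidates.  Vectorized with numpy so the
    all-vs-all stage is not quadratic in Python.
    """
    gene_idx: list[np.ndarray] = []
    pos_idx: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    alphabet = sorted({c for s in seqs for c in s})
    lut = {c: i for i, c in enumerate(alphabet)}
    base = len(lut)
    for gi, s in enumerate(seqs):
        if len(s) < k:
            continue
        enc = np.array([lut[c] for c in s], dtype=np.int64)
        mult = base ** np.arange(k, dtype=np.int64)
        code = np.convolve(enc, mult[::-1], mode="valid")
        codes.append(code)
        gene_idx.append(np.full(len(code), gi, dtype=np.int64))
        pos_idx.append(np.arange(len(code), dtype=np.int64))
    if not codes:
        return set()
    code = np.concatenate(codes)
    gene = np.concatenate(gene_idx)
    pos = np.concatenate(pos_idx)
    order = np.argsort(code, kind="stable")
    code, gene, pos = code[order], gene[order], pos[order]
    # group boundaries of equal k-mer codes
    starts = np.flatnonzero(np.r_[True, code[1:] != code[:-1]])
    ends = np.r_[starts[1:], len(code)]
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    diag: list[np.ndarray] = []
    for s0, e0 in zip(starts, ends):
        m = e0 - s0
        if m < 2 or m > 2000:  # skip unique and low-complexity blowups
            continue
        g = gene[s0:e0]
        p = pos[s0:e0]
        ii, jj = np.triu_indices(m, k=1)
        keep = g[ii] != g[jj]
        if not keep.any():
            continue
        ii, jj = ii[keep], jj[keep]
        gi, gj = g[ii], g[jj]
        pi, pj = p[ii], p[jj]
        swap = gi > gj
        gi2 = np.where(swap, gj, gi)
        gj2 = np.where(swap, gi, gj)
        d = np.where(swap, pj - pi, pi - pj)
        pair_i.append(gi2)
        pair_j.append(gj2)
        diag.append(d // diag_bucket)
    if not pair_i:
        return set()
    gi = np.concatenate(pair_i)
    gj = np.concatenate(pair_j)
    dg = np.concatenate(diag)
    key = (gi.astype(np.int64) * len(ids) + gj) * 10_000_000 + (dg + 5_000_000)
    uniq, counts = np.unique(key, return_counts=True)
    hits = uniq[counts >= min_hits]
    pairs = set()
    for h in hits:
        pg = h // 10_000_000
        pairs.add((int(pg // len(ids)), int(pg % len(ids))))
    return pairs


def find_paralog_pairs(
    proteins: dict[str, str],
    min_identity: float = 40.0,
    min_aln_len: int = 100,
    exhaustive: bool = False,
) -> list[tuple[str, str]]:
    """Unordered within-genome protein pairs passing the similarity gate.

    A pair qualifies when its best local alignment (Smith-Waterman
    with identity scoring and affine gaps) covers >= ``min_aln_len``
    aligned residue columns at >= ``min_identity`` percent identity.
    By default a shared-k-mer seed stage prefilters candidate pairs
    (sensitivity drops for pairs below roughly 45% identity, as with
    any seeded search); ``exhaustive=True`` aligns every pair.
    """
    ids = sorted(proteins)
    seqs = [proteins[i] for i in ids]
    if len(ids) < 2:
        return []
    if exhaustive:
        cand = {(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))}
    else:
        cand = _kmer_candidates(ids, seqs)
    aligner = _make_aligner("local")
    enc = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    out: list[tuple[str, str]] = []
    for i, j in sorted(cand):
        # ungapped screen for equal-length pairs: the best min_aln_len
        # window bounds what a gapped local alignment can reach, up to
        # indel rearrangement; only the ambiguous band goes to SW
        if len(seqs[i]) == len(seqs[j]) and len(seqs[i]) >= min_aln_len:
            match = (enc[i] == enc[j]).astype(np.int32)
            cs = np.concatenate([[0], np.cumsum(match)])
            w = min_aln_len
            best = (cs[w:] - cs[:-w]).max() / w
            if best * 100.0 >= min_identity:
                out.append((ids[i], ids[j]))
                continue
            if best * 100.0 < 0.8 * min_identity:
                continue
        try:
            aln = aligner.align(seqs[i], seqs[j])[0]
        except (IndexError, ValueError):
            continue
        ident, cols = alignment_identity(aln)
        if cols >= min_aln_len and ident * 100.0 >= min_identity:
            out.append((ids[i], ids[j]))
    return out


def check_id_correspondence(proteins: dict[str, str], coding: dict[str, str]) -> None:
    """Raise with the offending IDs when protein/coding FASTAs disagree."""
    missing = sorted(set(proteins) - set(coding))
    extra = sorted(set(coding) - set(proteins))
    if missing or extra:
        raise ValueError(
            "protein/coding ID mismatch; protein-only: %s; coding-only: %s"
            % (missing[:10], extra[:10])
        )


# ---------------------------------------------------------------------------
# codon alignment


def _codons_of(gene_id: str, cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError(f"coding length of {gene_id} not divisible by 3")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    for idx, c in enumerate(codons[:-1]):
        if is_stop(c):
            raise ValueError(f"internal stop codon in {gene_id} at codon {idx}")
    if codons and is_stop(codons[-1]):
        codons = codons[:-1]
    return codons


def align_proteins_global(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment as two gapped strings."""
    aligner = _make_aligner("global")
    aln = aligner.align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


def align_codons(
    pair_id: str,
    coding_a: str,
    coding_b: str,
    protein_alignment: tuple[str, str],
) -> CodonAlignment:
    """Back-translate a gapped protein alignment onto the coding sequences.

    Columns with a gap, an ambiguous base, or an unscorable codon in
    either gene are dropped.  A trailing stop codon on either CDS is
    tolerated (trimmed); an internal stop raises, naming the gene.
    """
    cod_a = _codons_of(pair_id.split("~")[0] if "~" in pair_id else "gene_a", coding_a)
    cod_b = _codons_of(pair_id.split("~")[-1] if "~" in pair_id else "gene_b", coding_b)
    ga, gb = protein_alignment
    if len(ga) != len(gb):
        raise ValueError("protein alignment rows differ in length")
    ia = ib = 0
    keep_a: list[str] = []
    keep_b: list[str] = []
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            if ia < len(cod_a) and ib < len(cod_b):
                ca, cb = cod_a[ia], cod_b[ib]
                if not (set(ca) | set(cb)) - set("ACGT") and not (
                    is_stop(ca) or is_stop(cb)
                ):
                    keep_a.append(ca)
                    keep_b.append(cb)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    if not keep_a:
        raise ValueError(f"no scorable codon columns for pair {pair_id}")
    return CodonAlignment(pair_id, keep_a, keep_b)


# ---------------------------------------------------------------------------
# Ks estimation


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); requires p < 3/4."""
    if p >= SATURATION_P:
        raise ValueError("proportion at or beyond JC saturation")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def estimate_ks(alignment: CodonAlignment, gene_a: str = "", gene_b: str = "") -> ParalogPair:
    """NG86 Ks/Ka with JC correction for one codon alignment.

    Sites are averaged over both sequences; columns where every
    mutational path runs through a stop are excluded entirely (sites
    and differences), which keeps S+N = 3 x scored columns and the
    estimate symmetric under swapping the two genes.
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    scored = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        d = ng86_differences(ca, cb)
        if d is None:
            continue
        scored += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        sd += d[0]
        nd += d[1]
    S = 0.5 * (s_a + s_b)
    N = 0.5 * (n_a + n_b)
    pair = ParalogPair(
        gene_a=gene_a or alignment.pair_id,
        gene_b=gene_b or alignment.pair_id,
        n_codons=scored,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
    )
    if S > 0:
        pair.pS = sd / S
    if N > 0:
        pair.pN = nd / N
    if pair.pS is None or pair.pS >= SATURATION_P or (
        pair.pN is not None and pair.pN >= SATURATION_P
    ):
        pair.saturated = True
    if pair.pS is not None and pair.pS < SATURATION_P:
        pair.Ks = jukes_cantor(pair.pS)
    if pair.pN is not None and pair.pN < SATURATION_P:
        pair.Ka = jukes_cantor(pair.pN)
    if pair.Ks is None:
        pair.saturated = True
    return pair


def estimate_pair_ks(
    gene_a: str,
    gene_b: str,
    coding: dict[str, str],
    proteins: dict[str, str],
) -> ParalogPair:
    """Convenience: global protein alignment -> codon alignment -> Ks."""
    pa = align_proteins_global(proteins[gene_a], proteins[gene_b])
    aln = align_codons(f"{gene_a}~{gene_b}", coding[gene_a], coding[gene_b], pa)
    return estimate_ks(aln, gene_a, gene_b)


# ---------------------------------------------------------------------------
# histogram


def build_ks_table(
    pairs: list[ParalogPair],
    ks_min: float = KS_MIN_DEFAULT,
    ks_max: float = KS_MAX_DEFAULT,
    bin_width: float = KS_BIN_WIDTH,
) -> tuple[KsHistogram, list[ParalogPair]]:
    """Filter to defined Ks within [ks_min, ks_max] and bin.

    Bins are left-closed right-open except the last, which is closed,
    so a Ks exactly at ks_max is counted.  Returns the histogram and
    the retained pairs (for downstream SiZer analysis).
    """
    n_bins = int(round((ks_max - ks_min) / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    kept: list[ParalogPair] = []
    for p in pairs:
        if p.saturated or p.Ks is None:
            continue
        if p.Ks < ks_min or p.Ks > ks_max:
            continue
        idx = min(int((p.Ks - ks_min) / bin_width), n_bins - 1)
        counts[idx] += 1
        kept.append(p)
    hist = KsHistogram(bin_width, ks_min, ks_max, counts, int(counts.sum()))
    return hist, kept


def ks_mode(values: np.ndarray, bandwidth: float | None = None, step: float = 0.005) -> float:
    """Mode of the paralog-age distribution.

    The raw histogram argmax is not a consistent location estimator at
    typical pair counts (adjacent 0.05 bins under a broad peak have
    near-equal expected counts, so the argmax jitters by several bin
    widths); the mode is therefore read off a Gaussian KDE at the
    Silverman bandwidth, evaluated on a fine grid over the Ks window.
    """
    from .sizer import silverman_bandwidth

    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty Ks sample")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(v)
    grid = np.arange(v.min(), v.max() + step, step)
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def pairs_to_rows(pairs: list[ParalogPair]) -> list[dict]:
    """Tabular form (one dict per pair) for the per-pair TSV output."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "n_codons": p.n_codons,
                "S": round(p.S, 6),
                "N": round(p.N, 6),
                "Sd": round(p.Sd, 6),
                "Nd": round(p.Nd, 6),
                "Ks": "." if p.Ks is None else round(p.Ks, 6),
                "Ka": "." if p.Ka is None else round(p.Ka, 6),
                "saturated": int(p.saturated),
            }
        )
    return rows
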