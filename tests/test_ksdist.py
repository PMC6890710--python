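"""Paralog pairing, codon alignment, Ks estimation and binning."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ploidyscape.ksdist import (
    CodonAlignment,
    ParalogPair,
    align_codons,
    align_proteins_global,
    build_ks_table,
    check_id_correspondence,
    estimate_ks,
    find_paralog_pairs,
    jukes_cantor,
    ks_mode,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# pure-Python Smith-Waterman oracle (affine gaps, identity scoring)


def sw_best_identity(a, b, match=2, mismatch=-1, gap_open=-8, gap_ext=-2):
    """Best local alignment by affine-gap SW; returns (identity, cols)
    of the traceback path.  Quadratic and independent of Bio.Align."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {}
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_ext, H[i][j - 1] + gap_open + gap_ext)
            F[i][j] = max(F[i - 1][j] + gap_ext, H[i - 1][j] + gap_open + gap_ext)
            sub = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            if H[i][j] == 0:
                ptr[(i, j)] = None
            elif H[i][j] == sub:
                ptr[(i, j)] = ("d", i - 1, j - 1)
            elif H[i][j] == E[i][j]:
                ptr[(i, j)] = ("l", i, j - 1)
            else:
                ptr[(i, j)] = ("u", i - 1, j)
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    matches = cols = 0
    i, j = bi, bj
    while (i, j) in ptr and ptr[(i, j)] is not None and H[i][j] > 0:
        kind, pi, pj = ptr[(i, j)]
        if kind == "d":
            cols += 1
            matches += a[i - 1] == b[j - 1]
        i, j = pi, pj
    return (matches / cols if cols else 0.0), cols


# ---------------------------------------------------------------------------
# pairing


def test_identical_proteins_form_one_pair():
    prot = {"a": "M" * 100 + "W" * 100, "b": "M" * 100 + "W" * 100}
    assert find_paralog_pairs(prot) == [("a", "b")]


def test_three_identical_genes_give_three_pairs():
    seq = "MAWPT" * 40
    prot = {f"g{i}": seq for i in range(3)}
    pairs = find_paralog_pairs(prot)
    assert sorted(pairs) == [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]


def test_unrelated_random_proteins_do_not_pair():
    rng = random.Random(3)
    prot = {
        "a": "".join(rng.choice(AA20) for _ in range(200)),
        "b": "".join(rng.choice(AA20) for _ in range(200)),
    }
    assert find_paralog_pairs(prot, exhaustive=True) == []
    # the independent SW oracle agrees there is no qualifying alignment
    ident, cols = sw_best_identity(prot["a"], prot["b"])
    assert not (cols >= 100 and ident >= 0.40)


def test_heuristic_pairing_agrees_with_exhaustive_on_small_input(small_families):
    _, _, proteins, truth = small_families
    ids = sorted(proteins)[:40]
    sub = {i: proteins[i] for i in ids}
    fast = set(find_paralog_pairs(sub))
    full = set(find_paralog_pairs(sub, exhaustive=True))
    assert fast == full


def test_id_mismatch_errors_name_offenders():
    with pytest.raises(ValueError, match="gene2"):
        check_id_correspondence({"gene1": "M", "gene2": "M"}, {"gene1": "ATG"})


# ---------------------------------------------------------------------------
# codon alignment


def test_identical_sequences_align_fully():
    cds = "ATGGGTACC"
    aln = align_codons("p", cds, cds, ("MGT", "MGT"))
    assert aln.n_codons == 3
    assert aln.codons_a == aln.codons_b == ["ATG", "GGT", "ACC"]


def test_gap_column_is_dropped():
    aln = align_codons("p", "ATGGGT", "ATGACCGGT", ("M-G", "MTG"))
    assert aln.n_codons == 2  # gapped column removed


def test_ambiguous_codon_column_is_dropped():
    aln = align_codons("p", "ATGGGN", "ATGGGT", ("MG", "MG"))
    assert aln.n_codons == 1


def test_internal_stop_is_rejected_with_gene_name():
    with pytest.raises(ValueError, match="stop"):
        align_codons("x~y", "TAAATG", "ATGATG", ("MM", "MM"))


def test_length_not_multiple_of_three_is_rejected():
    with pytest.raises(ValueError, match="divisible"):
        align_codons("x~y", "ATGGG", "ATGGGT", ("MG", "MG"))


# ---------------------------------------------------------------------------
# Ks estimation


def test_identical_sequences_have_zero_distance():
    aln = CodonAlignment("p", ["GGT", "ATG"], ["GGT", "ATG"])
    p = estimate_ks(aln)
    assert p.Ks == 0.0 and p.Ka == 0.0 and not p.saturated


def test_single_synonymous_change_matches_jc_arithmetic():
    """Nine GGT codons vs one GGT->GGC: S=9, Sd=1, pS=1/9, and the JC
    correction gives -(3/4) ln(1 - 4/27) = 0.120257 (independent
    arithmetic)."""
    aln = CodonAlignment("p", ["GGT"] * 9, ["GGT"] * 8 + ["GGC"])
    p = estimate_ks(aln)
    assert p.S == pytest.approx(9.0, abs=1e-12)
    assert p.Sd == pytest.approx(1.0, abs=1e-12)
    assert p.pS == pytest.approx(1.0 / 9.0, abs=1e-12)
    expected = -0.75 * math.log(1.0 - 4.0 / 27.0)
    assert p.Ks == pytest.approx(expected, abs=1e-12)
    assert p.Ks == pytest.approx(0.1202569875, abs=1e-9)


def test_saturated_alignment_is_flagged_with_undefined_ks():
    # GGN codons: third position differences are all synonymous; make
    # pS far beyond 3/4 by differing at every third position
    a = ["GGT"] * 20
    b = ["GGA"] * 20
    p = estimate_ks(CodonAlignment("p", a, b))
    assert p.pS == pytest.approx(1.0, abs=1e-12)
    assert p.saturated and p.Ks is None


def test_estimate_is_symmetric_under_swapping():
    rng = random.Random(5)
    fams = ["GCT", "GGA", "ACC", "TCG", "CCA", "GTT", "ATG", "TGG"]
    a = [rng.choice(fams) for _ in range(60)]
    b = [rng.choice(fams) for _ in range(60)]
    p1 = estimate_ks(CodonAlignment("p", a, b))
    p2 = estimate_ks(CodonAlignment("p", b, a))
    assert p1.S == p2.S and p1.Sd == p2.Sd
    assert p1.Ks == p2.Ks and p1.Ka == p2.Ka


@given(st.floats(min_value=1e-6, max_value=0.7499))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_jc_distance_is_monotone_and_exceeds_p(p):
    d = jukes_cantor(p)
    assert d >= p
    assert jukes_cantor(p * 0.5) < d


# ---------------------------------------------------------------------------
# histogram


def _pair(ks):
    pp = ParalogPair("a", "b", 10, 10.0, 20.0, 0.0, 0.0)
    pp.Ks = ks
    return pp


def test_histogram_counts_and_window():
    hist, kept = build_ks_table([_pair(0.12), _pair(0.14)])
    assert hist.counts[0] == 2
    assert hist.n_pairs == 2 == len(kept)
    assert hist.counts.sum() == hist.n_pairs


def test_value_below_window_is_excluded():
    hist, kept = build_ks_table([_pair(0.05)])
    assert hist.n_pairs == 0 and kept == []


def test_right_edge_is_included_in_final_bin():
    hist, kept = build_ks_table([_pair(2.1)])
    assert hist.n_pairs == 1
    assert hist.counts[-1] == 1


def test_saturated_pairs_are_excluded():
    sat = ParalogPair("a", "b", 10, 10.0, 20.0, 9.0, 0.0, saturated=True)
    hist, kept = build_ks_table([sat, _pair(1.0)])
    assert hist.n_pairs == 1


def test_ks_mode_locates_a_planted_bump():
    rng = np.random.default_rng(0)
    values = np.concatenate(
        [rng.normal(1.1, 0.12, 300), rng.uniform(0.1, 2.1, 300)]
    )
    assert abs(ks_mode(values) - 1.1) < 0.06
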