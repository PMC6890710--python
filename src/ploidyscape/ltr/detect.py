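"""Structural detection of paired-LTR retrotransposon candidates.

Seed-and-extend on the forward strand: exact ``seed_k``-mer matches
between positions whose separation lies within the LTR-start distance
window seed candidate LTR pairs; seeds sharing a diagonal are chained
and extended by an X-drop walk (the pair of LTR copies is compared
base-by-base along the diagonal; small indel variation is absorbed
later by the global alignment that computes pair identity).  A
candidate is accepted when both LTR lengths sit in the length window,
the pair identity meets the similarity floor, TG...CA termini are
found within ``vicinity`` bp of the extension boundaries (when the
motif is required), and identical ``tsd_len``-mers flank the element.
Conflicting candidates (overlapping LTR intervals) are resolved by
identity, then length, then leftmost position.
"""

from __future__ import annotations

import numpy as np

from .align import global_identity
from .params import LTRElement, LTRParams

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_T, _G, _C, _A = 3, 2, 1, 0


def encode_seq(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all N-free k-mers."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mult = 4 ** np.arange(k, dtype=np.int64)
    safe = np.where(arr == 4, 0, arr).astype(np.int64)
    codes = np.convolve(safe, mult[::-1], mode="valid")
    is_n = (arr == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.flatnonzero(valid)
    return codes[pos], pos


def _seed_pairs(arr: np.ndarray, params: LTRParams):
    """Seed pairs grouped by diagonal: {diag: sorted ltr5-side positions}."""
    codes, pos = _kmer_codes(arr, params.seed_k)
    if codes.size == 0:
        return {}
    order = np.argsort(codes, kind="stable")
    codes, pos = codes[order], pos[order]
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    ends = np.r_[starts[1:], codes.size]
    by_diag: dict[int, list[int]] = {}
    lo_d, hi_d = params.min_ltr_dist, params.max_ltr_dist
    for s0, e0 in zip(starts, ends):
        m = e0 - s0
        if m < 2 or m > 200:
            continue
        p = np.sort(pos[s0:e0])
        j0 = 0
        for i in range(m):
            for j in range(i + 1, m):
                d = int(p[j] - p[i])
                if d < lo_d:
                    continue
                if d > hi_d:
                    break
                by_diag.setdefault(d, []).append(int(p[i]))
    return by_diag


def _xdrop_extend(arr: np.ndarray, diag: int, a: int, b: int, xdrop: int = 20):
    """Extend the exact-match anchor [a, b) along ``diag`` in both
    directions; returns the best-scoring [s, e) on the 5' copy."""
    L = len(arr)

    def step_score(i: int) -> int:
        x, y = arr[i], arr[i + diag]
        if x == 4 or y == 4:
            return -3
        return 1 if x == y else -2

    # left
    best = 0
    score = 0
    s = a
    i = a - 1
    while i >= 0 and i + diag < L and best - score < xdrop:
        score += step_score(i)
        if score > best:
            best = score
            s = i
        i -= 1
    # right
    best = 0
    score = 0
    e = b
    i = b
    while i + diag < L and i < s + diag and best - score < xdrop:
        score += step_score(i)
        if score > best:
            best = score
            e = i + 1
        i += 1
    e = min(e, s + diag)  # LTR copies must not overlap
    return s, e


def _motif_starts(arr: np.ndarray, pos: int, diag: int, vic: int) -> list[int]:
    """Element-start candidates near ``pos`` where both LTR copies begin
    with TG, nearest first."""
    L = len(arr)
    out = []
    for delta in sorted(range(-vic, vic + 1), key=abs):
        p = pos + delta
        if (
            0 <= p
            and p + diag + 1 < L
            and arr[p] == _T
            and arr[p + 1] == _G
            and arr[p + diag] == _T
            and arr[p + diag + 1] == _G
        ):
            out.append(p)
    return out


def _motif_ends(arr: np.ndarray, pos: int, diag: int, vic: int) -> list[int]:
    """Element-end (exclusive) candidates near ``pos`` where both LTR
    copies end with CA, nearest first."""
    L = len(arr)
    out = []
    for delta in sorted(range(-vic, vic + 1), key=abs):
        p = pos + delta
        if (
            p - diag - 2 >= 0
            and p <= L
            and arr[p - 2] == _C
            and arr[p - 1] == _A
            and arr[p - diag - 2] == _C
            and arr[p - diag - 1] == _A
        ):
            out.append(p)
    return out


def _tsd_at(arr: np.ndarray, s: int, elem_end: int, t: int) -> bool:
    if s - t < 0 or elem_end + t > len(arr):
        return False
    t1 = arr[s - t : s]
    t2 = arr[elem_end : elem_end + t]
    return bool((t1 == t2).all() and (t1 != 4).all())


def find_ltr_candidates(genome: dict[str, str], params: LTRParams) -> list[LTRElement]:
    """Scan each contig for structurally valid paired-LTR candidates."""
    params.validate()
    out: list[LTRElement] = []
    for contig in sorted(genome):
        seq = genome[contig]
        arr = encode_seq(seq)
        by_diag = _seed_pairs(arr, params)
        cands: list[LTRElement] = []
        for diag in sorted(by_diag):
            positions = sorted(set(by_diag[diag]))
            clusters: list[list[int]] = [[positions[0]]]
            for p in positions[1:]:
                if p - clusters[-1][-1] > params.max_ltr_len:
                    clusters.append([p])
                else:
                    clusters[-1].append(p)
            for cl in clusters:
                a, b = cl[0], cl[-1] + params.seed_k
                s, e = _xdrop_extend(arr, diag, a, b)
                elem_end = e + diag  # exclusive
                motif_ok = False
                if params.motif:
                    # a TSD-validated TG/CA combination may sit slightly
                    # beyond the nominal vicinity when the X-drop walk
                    # overshoots a boundary; the TSD anchors the truth
                    wide = params.vicinity + params.tsd_len + 10
                    starts_w = _motif_starts(arr, s, diag, wide)
                    ends_w = _motif_ends(arr, elem_end, diag, wide)
                    chosen = None
                    for me in ends_w:
                        for ms in starts_w:
                            if _tsd_at(arr, ms, me, params.tsd_len):
                                chosen = (ms, me)
                                break
                        if chosen:
                            break
                    if chosen is None:
                        starts = _motif_starts(arr, s, diag, params.vicinity)
                        ends = _motif_ends(arr, elem_end, diag, params.vicinity)
                        if starts and ends:
                            chosen = (starts[0], ends[0])
                    if chosen is not None:
                        s, elem_end = chosen
                        e = elem_end - diag
                        motif_ok = True
                    elif params.require_motif:
                        continue
                ltr_len = e - s
                if not params.min_ltr_len <= ltr_len <= params.max_ltr_len:
                    continue
                if not params.min_ltr_dist <= diag <= params.max_ltr_dist:
                    continue
                # target-site duplication
                t = params.tsd_len
                tsd = ""
                if _tsd_at(arr, s, elem_end, t):
                    tsd = seq[s - t : s].upper()
                if params.require_tsd and not tsd:
                    continue
                ident, _ = global_identity(seq[s:e], seq[s + diag : elem_end])
                if ident < params.min_similarity:
                    continue
                cands.append(
                    LTRElement(
                        element_id="",
                        contig=contig,
                        ltr5=(s, e),
                        ltr3=(s + diag, elem_end),
                        tsd=tsd,
                        motif_ok=motif_ok,
                        ltr_identity=ident,
                    )
                )
        out.extend(_dedup(cands))
    for i, el in enumerate(sorted(out, key=lambda e: (e.contig, e.start))):
        el.element_id = f"cand{i:04d}"
    return sorted(out, key=lambda e: (e.contig, e.start))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _conflicts(a: LTRElement, b: LTRElement) -> bool:
    return (
        _overlaps(a.ltr5, b.ltr5)
        or _overlaps(a.ltr3, b.ltr3)
        or _overlaps(a.ltr5, b.ltr3)
        or _overlaps(a.ltr3, b.ltr5)
    )


def _dedup(cands: list[LTRElement]) -> list[LTRElement]:
    """Resolve candidates with overlapping LTR intervals.

    Minimum-conflict-first greedy: repeatedly keep the remaining
    candidate in conflict with the fewest others (ties broken by
    higher identity, then length, then leftmost) and discard its
    conflictees.  Preferring low-conflict candidates dismantles
    chimeric pairings — e.g. one element's 3' LTR matched against a
    same-family neighbor's 5' LTR, which conflicts with both genuine
    elements while each genuine element conflicts only with the
    chimera.
    """
    remaining = list(cands)
    kept: list[LTRElement] = []
    while remaining:
        degree = {
            id(c): sum(1 for o in remaining if o is not c and _conflicts(c, o))
            for c in remaining
        }
        best = min(
            remaining,
            key=lambda c: (
                degree[id(c)],
                -c.ltr_identity,
                -(c.end - c.start),
                c.start,
            ),
        )
        kept.append(best)
        remaining = [c for c in remaining if c is not best and not _conflicts(best, c)]
    return sorted(kept, key=lambda c: c.start)
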