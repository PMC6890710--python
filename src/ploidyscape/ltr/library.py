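"""Exemplar libraries, recent/ancient classification, soft-masking.

Exemplars are cluster representatives from greedy centroid clustering
(longest first, join the first exemplar met at >= identity over >=
coverage of the shorter sequence), run first on internal sequences and
then, for elements without a usable internal region, on LTR sequences.
The recent/ancient split follows the two-pass collection protocol:
recent elements have >= 90% LTR-pair identity and the TG...CA motif;
ancient elements sit at 75-90% identity (motif not required) and are
excluded when they match a recent exemplar at the clustering
thresholds — the masking-exclusion step that keeps young copies out of
the ancient library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import local_identity_coverage
from .detect import encode_seq, _kmer_codes
from .filters import element_internal_seq
from .params import LTRElement, LTRParams


@dataclass
class Exemplar:
    exemplar_id: str
    element_id: str
    sequence: str          # clustering-basis sequence of the representative
    basis: str             # "internal" or "ltr"
    label: str = ""        # age class of the cluster
    members: list[str] = field(default_factory=list)
    full_sequence: str = ""  # whole element span (for masking); falls
                             # back to ``sequence`` when empty


@dataclass
class ExemplarLibrary:
    identity: float
    coverage: float
    exemplars: list[Exemplar] = field(default_factory=list)

    def assignment(self) -> dict[str, str]:
        out = {}
        for ex in self.exemplars:
            for m in ex.members:
                out[m] = ex.exemplar_id
        return out


def similar_sequences(
    a: str, b: str, identity: float, coverage: float
) -> bool:
    """Does the best local match of a vs b reach the identity threshold
    over the coverage share of the shorter sequence?  Short pairs use
    exact Smith-Waterman; long pairs use the seed-and-extend estimate
    (exact alignment on multi-kb internals is quadratic and the
    clustering decision only needs hit coverage and identity)."""
    if min(len(a), len(b)) <= 1500:
        ident, cov = local_identity_coverage(a, b)
    else:
        ident, cov = kmer_identity_coverage(encode_seq(a), encode_seq(b))
    return ident >= identity and cov >= coverage


def _element_full_seq(el: LTRElement, genome: dict[str, str]) -> str:
    seq = genome[el.contig]
    if el.excised:
        xlo, xhi = el.excised
        return seq[el.start : xlo] + seq[xhi : el.end]
    return seq[el.start : el.end]


def build_exemplars(
    elements: list[LTRElement],
    genome: dict[str, str],
    identity: float = 80.0,
    coverage: float = 90.0,
    label: str = "",
) -> ExemplarLibrary:
    """Greedy centroid clustering of elements into exemplars."""
    lib = ExemplarLibrary(identity=identity, coverage=coverage)
    with_internal = []
    ltr_only = []
    for el in elements:
        iseq = element_internal_seq(el, genome)
        if len(iseq) >= 50:
            with_internal.append((el, iseq))
        else:
            ltr_only.append(el)

    def greedy(items: list[tuple[LTRElement, str]], basis: str) -> None:
        for el, seq in sorted(items, key=lambda t: -len(t[1])):
            placed = False
            for ex in lib.exemplars:
                if ex.basis != basis:
                    continue
                if similar_sequences(seq, ex.sequence, identity, coverage):
                    ex.members.append(el.element_id)
                    placed = True
                    break
            if not placed:
                lib.exemplars.append(
                    Exemplar(
                        exemplar_id=f"ex{len(lib.exemplars):03d}",
                        element_id=el.element_id,
                        sequence=seq,
                        basis=basis,
                        label=label,
                        members=[el.element_id],
                        full_sequence=_element_full_seq(el, genome),
                    )
                )

    greedy(with_internal, "internal")
    greedy(
        [
            (el, genome[el.contig][el.ltr5[0] : el.ltr5[1]])
            for el in ltr_only
        ],
        "ltr",
    )
    return lib


def classify_age_class(
    elements: list[LTRElement],
    genome: dict[str, str],
    params: LTRParams,
) -> tuple[list[LTRElement], list[LTRElement], ExemplarLibrary]:
    """Split elements into recent and ancient classes.

    Returns (recent, ancient, recent-exemplar library).  Elements below
    the ancient identity floor, or in the ancient band but matching a
    recent exemplar, are dropped (age_class left empty).
    """
    recent = [
        el
        for el in elements
        if el.ltr_identity >= params.min_similarity and el.motif_ok
    ]
    for el in recent:
        el.age_class = "recent"
    recent_lib = build_exemplars(recent, genome, label="recent")
    ancient = []
    for el in elements:
        if el in recent:
            continue
        if not (
            params.ancient_min_similarity
            <= el.ltr_identity
            < params.ancient_max_similarity
        ):
            continue
        seq = element_internal_seq(el, genome) or genome[el.contig][
            el.ltr5[0] : el.ltr5[1]
        ]
        masked = False
        for ex in recent_lib.exemplars:
            if similar_sequences(
                seq, ex.sequence, recent_lib.identity, recent_lib.coverage
            ):
                masked = True
                break
        if not masked:
            el.age_class = "ancient"
            ancient.append(el)
    return recent, ancient, recent_lib


def kmer_identity_coverage(
    a_arr: np.ndarray, b_arr: np.ndarray, k: int = 13, xdrop: int = 15
) -> tuple[float, float]:
    """Seed-and-extend estimate of (percent identity, percent coverage
    of the shorter sequence) between two nucleotide arrays."""
    target, query = (a_arr, b_arr) if len(a_arr) <= len(b_arr) else (b_arr, a_arr)
    tcodes, tpos = _kmer_codes(target, k)
    qcodes, qpos = _kmer_codes(query, k)
    if tcodes.size == 0 or qcodes.size == 0:
        return 0.0, 0.0
    order = np.argsort(tcodes, kind="stable")
    tcodes_s, tpos_s = tcodes[order], tpos[order]
    lo = np.searchsorted(tcodes_s, qcodes, side="left")
    hi = np.searchsorted(tcodes_s, qcodes, side="right")
    import bisect

    covered: list[tuple[int, int]] = []
    matches_total = 0
    cols_total = 0
    seeds: list[tuple[int, int]] = []
    for qi in np.flatnonzero(hi > lo):
        if hi[qi] - lo[qi] > 100:
            continue
        for tj in range(lo[qi], hi[qi]):
            seeds.append((int(qpos[qi]), int(tpos_s[tj])))
    for q0, t0 in sorted(seeds, key=lambda s: s[1]):
        idx = bisect.bisect_right(covered, (t0, float("inf"))) - 1
        if idx >= 0 and covered[idx][1] >= t0 + k:
            continue
        s_t, e_t, ident = _extend_pair(target, query, t0, q0, k, xdrop)
        if e_t - s_t >= k:
            matches_total += int(round(ident * (e_t - s_t)))
            cols_total += e_t - s_t
            covered = _merge(covered + [(s_t, e_t)])
    if cols_total == 0:
        return 0.0, 0.0
    cov_bp = sum(h - l for l, h in covered)
    return (
        100.0 * matches_total / cols_total,
        100.0 * cov_bp / len(target),
    )


# ---------------------------------------------------------------------------
# soft-masking


def _hit_intervals(
    target: np.ndarray,
    query: np.ndarray,
    k: int = 15,
    xdrop: int = 15,
    min_identity: float = 80.0,
    min_len: int = 100,
) -> list[tuple[int, int]]:
    """Seed-and-extend local hits of query in target (forward strand)."""
    tcodes, tpos = _kmer_codes(target, k)
    qcodes, qpos = _kmer_codes(query, k)
    if tcodes.size == 0 or qcodes.size == 0:
        return []
    order = np.argsort(tcodes, kind="stable")
    tcodes_s, tpos_s = tcodes[order], tpos[order]
    hits: list[tuple[int, int]] = []
    covered: list[tuple[int, int]] = []
    lo = np.searchsorted(tcodes_s, qcodes, side="left")
    hi = np.searchsorted(tcodes_s, qcodes, side="right")
    seeds: list[tuple[int, int]] = []
    for qi in np.flatnonzero(hi > lo):
        if hi[qi] - lo[qi] > 400:
            continue
        q0 = int(qpos[qi])
        for tj in range(lo[qi], hi[qi]):
            seeds.append((q0, int(tpos_s[tj])))
    # extend seeds not already inside a found hit; covered intervals are
    # kept merged and sorted so the inside test is a bisect
    import bisect

    for q0, t0 in sorted(seeds, key=lambda s: s[1]):
        idx = bisect.bisect_right(covered, (t0, float("inf"))) - 1
        if idx >= 0 and covered[idx][1] >= t0 + k:
            continue
        s_t, e_t, ident = _extend_pair(target, query, t0, q0, k, xdrop)
        if e_t - s_t >= min_len and ident * 100.0 >= min_identity:
            hits.append((s_t, e_t))
            merged = _merge(covered + [(s_t, e_t)])
            covered.clear()
            covered.extend(merged)
    return _merge(hits)


def _extend_pair(target, query, t0, q0, k, xdrop):
    matches = k
    total = k
    # left
    best = 0
    score = 0
    s_t, s_q = t0, q0
    i, jq = t0 - 1, q0 - 1
    bm = 0
    m = 0
    while i >= 0 and jq >= 0 and best - score < xdrop:
        good = target[i] != 4 and query[jq] != 4 and target[i] == query[jq]
        score += 1 if good else -2
        m += 1 if good else 0
        if score > best:
            best, s_t, bm = score, i, m
        i -= 1
        jq -= 1
    matches += bm
    total += t0 - s_t
    # right
    best = 0
    score = 0
    e_t = t0 + k
    i, jq = t0 + k, q0 + k
    bm = 0
    m = 0
    while i < len(target) and jq < len(query) and best - score < xdrop:
        good = target[i] != 4 and query[jq] != 4 and target[i] == query[jq]
        score += 1 if good else -2
        m += 1 if good else 0
        if score > best:
            best, e_t, bm = score, i + 1, m
        i += 1
        jq += 1
    matches += bm
    total += e_t - (t0 + k)
    return s_t, e_t, matches / total if total else 0.0


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(lo, hi) for lo, hi in out]


def mask_genome(
    genome: dict[str, str],
    library: ExemplarLibrary,
    min_hit_identity: float = 80.0,
    min_hit_len: int = 100,
) -> tuple[dict[str, str], list[dict]]:
    """Soft-mask (lowercase) genome regions hit by library exemplars.

    Returns the masked genome and a hit annotation (contig, start, end,
    exemplar basis/label), overlapping hits merged per contig.
    Idempotent: case of unhit regions is preserved, hit regions are
    lowercased regardless of prior case.
    """
    masked: dict[str, str] = {}
    annotation: list[dict] = []
    for contig in sorted(genome):
        seq = genome[contig]
        arr = encode_seq(seq)
        all_hits: list[tuple[int, int]] = []
        for ex in library.exemplars:
            q = encode_seq(ex.full_sequence or ex.sequence)
            all_hits.extend(
                _hit_intervals(
                    arr, q, min_identity=min_hit_identity, min_len=min_hit_len
                )
            )
        merged = _merge(all_hits)
        chars = list(seq)
        for lo, hi in merged:
            chars[lo:hi] = seq[lo:hi].lower()
            annotation.append(
                {"contig": contig, "start": lo, "end": hi, "label": "LTR/unknown"}
            )
        masked[contig] = "".join(chars)
    return masked, annotation
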