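"""False-positive filters over detected LTR candidates.

Three filters mirror the post-LTRharvest cleanup: gappy elements
(a run of more than ``max_n_run`` Ns inside the element), recent
tandem gene duplications (the regions flanking the two LTRs are
alignable, which a genuine insertion into unrelated host sequence
never shows), and nested insertions (a candidate wholly inside
another candidate's internal region — the inner element is kept as
its own element and the outer is reported with the nested span
excised so downstream identity/dating work on its own sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import flank_identity as _flank_window_identity
from .params import LTRElement


@dataclass
class Rejection:
    element: LTRElement
    reason: str


def _max_n_run(seq: str) -> int:
    best = run = 0
    for ch in seq:
        if ch in "Nn":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def filter_candidates(
    candidates: list[LTRElement],
    genome: dict[str, str],
    flank_window: int = 50,
    flank_identity: float = 60.0,
    max_n_run: int = 50,
) -> tuple[list[LTRElement], list[Rejection]]:
    """Apply the gappy / alignable-flank / nested filters.

    Returns (kept, rejected-with-reasons).  Nested candidates are not
    rejections: both elements stay, the outer flagged ``nested`` with
    the excised span (inner element plus one TSD copy) recorded.
    """
    # nested marking first: the outer's own body excludes the inserted
    # span, so an N-gap inside a nested element does not disqualify its
    # host and the outer's identity/dating use its own sequence
    for outer in candidates:
        ilo, ihi = outer.internal
        for inner in candidates:
            if inner is outer or inner.contig != outer.contig:
                continue
            if ilo <= inner.start and inner.end <= ihi:
                outer.flags.add("nested")
                t = len(inner.tsd)
                outer.excised = (inner.start, inner.end + t)
                inner.flags.add("nested_inner")
    kept: list[LTRElement] = []
    rejected: list[Rejection] = []
    for el in candidates:
        seq = genome[el.contig]
        if el.excised:
            body = seq[el.start : el.excised[0]] + seq[el.excised[1] : el.end]
        else:
            body = seq[el.start : el.end]
        if _max_n_run(body) > max_n_run:
            el.flags.add("gappy")
            rejected.append(Rejection(el, "gappy"))
            continue
        w = flank_window
        up5 = seq[max(el.ltr5[0] - w, 0) : el.ltr5[0]]
        up3 = seq[max(el.ltr3[0] - w, 0) : el.ltr3[0]]
        dn5 = seq[el.ltr5[1] : el.ltr5[1] + w]
        dn3 = seq[el.ltr3[1] : el.ltr3[1] + w]
        id_up = _flank_window_identity(up5, up3)
        id_dn = _flank_window_identity(dn5, dn3)
        if id_up > flank_identity or id_dn > flank_identity:
            el.flags.add("alignable_flanks")
            rejected.append(Rejection(el, "alignable_flanks"))
            continue
        kept.append(el)
    return kept, rejected


def element_internal_seq(el: LTRElement, genome: dict[str, str]) -> str:
    """Internal-region sequence with any nested span removed."""
    seq = genome[el.contig]
    lo, hi = el.internal
    if el.excised:
        xlo, xhi = el.excised
        return seq[lo : max(xlo, lo)] + seq[min(xhi, hi) : hi]
    return seq[lo:hi]
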