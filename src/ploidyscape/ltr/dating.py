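"""Jukes-Cantor dating of LTR-pair divergence.

The two terminal repeats of an element are identical at insertion and
diverge neutrally afterwards, so their corrected distance d divided by
twice the substitution rate (both repeats accumulate change) estimates
years since insertion: p = mismatches / aligned non-gap non-N sites,
d = -(3/4) ln(1 - (4/3) p), T = d / (2 mu).
"""

from __future__ import annotations

import math

from .align import global_mismatch_stats
from .params import InsertionAge, LTRElement

DEFAULT_MU = 6.5e-9  # substitutions / site / year, neutral plant rate


def jc_age(p: float, mu: float = DEFAULT_MU) -> tuple[float | None, float | None]:
    """(d, T) from a mismatch proportion; (None, None) when saturated."""
    if p >= 0.75:
        return None, None
    d = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return d, d / (2.0 * mu)


def dateable(el: LTRElement) -> bool:
    """Full-length, high-confidence restriction: recent class, intact
    motif, no gap corruption."""
    return el.age_class == "recent" and el.motif_ok and "gappy" not in el.flags


def date_insertions(
    elements: list[LTRElement],
    genome: dict[str, str],
    mu: float = DEFAULT_MU,
    strict: bool = True,
) -> list[InsertionAge]:
    """Global-align each element's LTR pair and convert divergence to
    years.  With ``strict`` only elements passing :func:`dateable` are
    dated; saturated pairs are reported flagged, with no age."""
    ages: list[InsertionAge] = []
    for el in elements:
        if strict and not dateable(el):
            continue
        seq = genome[el.contig]
        a = seq[el.ltr5[0] : el.ltr5[1]]
        b = seq[el.ltr3[0] : el.ltr3[1]]
        mism, cols = global_mismatch_stats(a, b)
        p = mism / cols if cols else 1.0
        d, T = jc_age(p, mu)
        sat = d is None
        ages.append(
            InsertionAge(
                element_id=el.element_id,
                p=p,
                d=d,
                mu=mu,
                T=T,
                n_sites=cols,
                saturated=sat,
            )
        )
        el.age_years = T
        el.age_saturated = sat
    return ages
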