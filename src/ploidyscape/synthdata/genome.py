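"""Synthetic genome with planted LTR retrotransposons.

Each element is TSD + 5'LTR + internal + 3'LTR + TSD.  The two LTRs
start identical (one family-ancestral sequence with TG...CA termini)
and each copy then receives a deterministic round(age x subst_rate x
length) count of Jukes-Cantor substitution events at uniform random
sites (multiple hits allowed), so the planted age is exactly the
quantity JC dating of the LTR pair estimates.  The 2-bp termini are
excluded from mutation: integrase function constrains them in real
elements, and keeping them intact makes the TG...CA motif a structural
invariant of planted elements.

Also planted: nested insertions (a younger element spliced into an
older element's internal region, with its own target-site duplication;
LTRs are never split), >50-N gap corruption of element bodies, and
tandem-duplication decoys whose two copies have byte-identical flanks
(built to pass the structural LTR screen and trip the alignable-flank
filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .truth import ElementTruth, TruthTable

_ALPH = np.frombuffer(b"ACGTN", dtype=np.uint8)
_MIN_GAP = 200  # bp of background between planted blocks


def _decode(arr: np.ndarray) -> str:
    return _ALPH[arr].tobytes().decode()


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _jc_events(
    rng: np.random.Generator,
    seq: np.ndarray,
    n_events: int,
    protect: int = 0,
) -> np.ndarray:
    """Apply n_events JC substitutions at uniform sites (multiple hits
    allowed), sparing ``protect`` bp at each end."""
    out = seq.copy()
    lo, hi = protect, len(seq) - protect
    if hi <= lo or n_events <= 0:
        return out
    sites = rng.integers(lo, hi, size=n_events)
    shifts = rng.integers(1, 4, size=n_events)
    for s, d in zip(sites, shifts):
        out[s] = (out[s] + d) % 4
    return out


@dataclass
class _Elem:
    eid: str
    family: int
    age: float
    tsd: np.ndarray
    ltr5: np.ndarray
    internal: list = field(default_factory=list)  # arrays or nested _Elem
    ltr3: np.ndarray | None = None
    gappy: bool = False
    nested_in: str | None = None
    has_nested: bool = False

    def core_len(self) -> int:
        n = len(self.ltr5) + len(self.ltr3)
        for part in self.internal:
            if isinstance(part, _Elem):
                n += part.core_len()
            else:
                n += len(part)
        return n


def _element_core(
    rng: np.random.Generator,
    eid: str,
    family: int,
    age: float,
    fam_ltr: np.ndarray,
    fam_internal: np.ndarray,
    subst_rate: float,
    gap_prob: float,
) -> _Elem:
    n_ltr = int(round(age * subst_rate * len(fam_ltr)))
    n_int = int(round(age * subst_rate * len(fam_internal)))
    ltr5 = _jc_events(rng, fam_ltr, n_ltr, protect=2)
    ltr3 = _jc_events(rng, fam_ltr, n_ltr, protect=2)
    internal = _jc_events(rng, fam_internal, n_int)
    gappy = False
    if rng.random() < gap_prob and len(internal) > 200:
        run = int(rng.integers(60, 151))
        pos = int(rng.integers(10, len(internal) - run - 10))
        internal[pos : pos + run] = 4  # N
        gappy = True
    return _Elem(
        eid=eid,
        family=family,
        age=age,
        tsd=np.empty(0, dtype=np.uint8),
        ltr5=ltr5,
        internal=[internal],
        ltr3=ltr3,
        gappy=gappy,
    )


def _flatten_core(elem: _Elem, start: int, truth: TruthTable, contig: str) -> list[np.ndarray]:
    """Emit the core (ltr5+internal+ltr3) arrays, recording truth
    coordinates (0-based half-open) from ``start``."""
    parts = [elem.ltr5]
    pos = start + len(elem.ltr5)
    ltr5_iv = (start, pos)
    for part in elem.internal:
        if isinstance(part, _Elem):
            sub = _flatten_core(part, pos, truth, contig)
            parts.extend(sub)
            pos += part.core_len()
        else:
            parts.append(part)
            pos += len(part)
    ltr3_iv = (pos, pos + len(elem.ltr3))
    parts.append(elem.ltr3)
    truth.element_truth[elem.eid] = ElementTruth(
        element_id=elem.eid,
        contig=contig,
        ltr5=ltr5_iv,
        ltr3=ltr3_iv,
        tsd=_decode(elem.tsd) if len(elem.tsd) else "",
        age_years=elem.age,
        nested_in=elem.nested_in,
        family=elem.family,
        gappy=elem.gappy,
    )
    return parts


def simulate_ltr_genome(config: SimConfig) -> tuple[dict[str, str], TruthTable]:
    """Genome FASTA records (one contig) and truth table / GFF3 rows."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    contig = "chr1"
    gc = config.gc_content

    # one ancestral LTR + internal per element family
    fams = []
    for _ in range(max(config.n_element_families, 1)):
        ltr_len = int(rng.integers(config.ltr_len_range[0], config.ltr_len_range[1] + 1))
        int_len = int(
            rng.integers(config.internal_len_range[0], config.internal_len_range[1] + 1)
        )
        ltr = _random_seq(rng, ltr_len, gc)
        ltr[0:2] = [3, 2]          # TG
        ltr[-2:] = [1, 0]          # CA
        fams.append((ltr, _random_seq(rng, int_len, gc)))

    truth = TruthTable()
    top_level: list[_Elem] = []
    for i in range(config.n_elements):
        eid = f"LTR{i:04d}"
        family = int(rng.integers(0, len(fams)))
        age = float(rng.uniform(*config.age_range))
        host: _Elem | None = None
        if top_level and rng.random() < config.nest_prob:
            eligible = [
                e
                for e in top_level
                if not e.has_nested
                and isinstance(e.internal[0], np.ndarray)
                and len(e.internal[0]) > 2 * 10 + config.tsd_len
                and e.core_len() - len(e.ltr3)
                + len(fams[family][0]) * 2 + len(fams[family][1]) + config.tsd_len
                <= SimConfig.MAX_LTR_DIST
            ]
            if eligible:
                host = eligible[int(rng.integers(0, len(eligible)))]
                age = float(rng.uniform(0.0, host.age)) if host.age > 0 else 0.0
        elem = _element_core(
            rng, eid, family, age, *fams[family], config.subst_rate, config.gap_prob
        )
        if host is None:
            elem.tsd = _random_seq(rng, config.tsd_len, gc)
            top_level.append(elem)
        else:
            hint = host.internal[0]
            pos = int(rng.integers(10, len(hint) - config.tsd_len - 10))
            tsd = hint[pos : pos + config.tsd_len].copy()
            elem.tsd = tsd
            elem.nested_in = host.eid
            host.internal = [
                hint[: pos + config.tsd_len],
                elem,
                tsd,
                hint[pos + config.tsd_len :],
            ]
            host.has_nested = True

    # tandem-gene-duplication decoys: two identical TG...CA-bounded
    # gene copies whose 50-bp flank windows are largely shared (they
    # trip the alignable-flank filter) but whose first ~15 bp beyond
    # each copy are copy-private, so seed extension stops at the gene
    # boundaries and the pair presents as a structurally valid element
    decoy_blocks: list[tuple[str, np.ndarray, int, int]] = []
    g_len = int(np.clip((config.ltr_len_range[0] + config.ltr_len_range[1]) // 2, 100, 6000))
    t = config.tsd_len
    sh_len = max(400, (SimConfig.MIN_LTR_DIST + 40 - g_len - 35 - 2 * t) // 2 + 20)
    for i in range(config.decoy_count):
        u_sh = _random_seq(rng, sh_len, gc)
        d_sh = _random_seq(rng, sh_len, gc)
        # copy-private spacers of unequal length keep the shared flank
        # segments off the gene pair's diagonal
        u1p, u2p = _random_seq(rng, 15, gc), _random_seq(rng, 19, gc)
        d1p, d2p = _random_seq(rng, 15, gc), _random_seq(rng, 12, gc)
        tsd = _random_seq(rng, t, gc)
        g = _random_seq(rng, g_len, gc)
        g[0:2] = [3, 2]
        g[-2:] = [1, 0]
        block = np.concatenate(
            [u_sh, u1p, tsd, g, d1p, d_sh, u_sh, u2p, tsd, g, tsd, d2p, d_sh]
        )
        g1_off = sh_len + 15 + t
        g2_off = g1_off + g_len + 15 + sh_len + sh_len + 19 + t
        decoy_blocks.append((f"DECOY{i:02d}", block, g1_off, g2_off))

    # assemble: background gaps + blocks
    blocks: list[tuple[str, object]] = [("elem", e) for e in top_level] + [
        ("decoy", b) for b in decoy_blocks
    ]
    order = rng.permutation(len(blocks))
    blocks = [blocks[j] for j in order]
    block_lens = []
    for kind, b in blocks:
        if kind == "elem":
            block_lens.append(b.core_len() + 2 * len(b.tsd))
        else:
            block_lens.append(len(b[1]))
    free = config.genome_len - sum(block_lens)
    n_gaps = len(blocks) + 1
    if free < n_gaps * _MIN_GAP:
        raise ValueError(
            f"infeasible packing: {sum(block_lens)} planted bp + minimum gaps "
            f"exceed genome_len={config.genome_len}"
        )
    extra = free - n_gaps * _MIN_GAP
    gap_lens = (
        rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps)) + _MIN_GAP
        if extra > 0
        else np.full(n_gaps, _MIN_GAP)
    )

    parts: list[np.ndarray] = []
    pos = 0
    for (kind, b), gap in zip(blocks, gap_lens[:-1]):
        parts.append(_random_seq(rng, int(gap), gc))
        pos += int(gap)
        if kind == "elem":
            parts.append(b.tsd)
            pos += len(b.tsd)
            parts.extend(_flatten_core(b, pos, truth, contig))
            pos += b.core_len()
            parts.append(b.tsd)
            pos += len(b.tsd)
        else:
            did, arr, g1_off, g2_off = b
            parts.append(arr)
            truth.element_truth[did] = ElementTruth(
                element_id=did,
                contig=contig,
                ltr5=(pos + g1_off, pos + g1_off + g_len),
                ltr3=(pos + g2_off, pos + g2_off + g_len),
                tsd=_decode(arr[g1_off - config.tsd_len : g1_off]),
                age_years=0.0,
                family=-1,
                kind="decoy",
            )
            pos += len(arr)
    parts.append(_random_seq(rng, int(gap_lens[-1]), gc))
    genome = _decode(np.concatenate(parts)) if parts else ""
    return {contig: genome}, truth
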