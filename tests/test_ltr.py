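"""Structural LTR detection, filtering, classification, dating,
exemplars, masking, and the repeat summary."""

import math

import numpy as np
import pytest

from ploidyscape.ltr import (
    LTRParams,
    build_exemplars,
    classify_age_class,
    date_insertions,
    filter_candidates,
    find_ltr_candidates,
    jc_age,
    mask_genome,
    summarize_repeats,
)
from ploidyscape.ltr.params import LTRElement
from ploidyscape.pipeline import run_ltr
from ploidyscape.synthdata import SimConfig, simulate_ltr_genome


def _match(cand, truth, tol=5):
    return abs(cand.start - truth.start) <= tol and abs(cand.end - truth.end) <= tol


# ---------------------------------------------------------------------------
# detection


def test_planted_elements_recovered_with_tight_boundaries(small_genome):
    cfg, genome, truth = small_genome
    cands = find_ltr_candidates(genome, LTRParams())
    elements = [t for t in truth.element_truth.values() if t.kind == "element"]
    found = 0
    for t in elements:
        hit = next((c for c in cands if _match(c, t)), None)
        if hit:
            found += 1
            assert abs(hit.ltr5[1] - t.ltr5[1]) <= 5
            assert abs(hit.ltr3[0] - t.ltr3[0]) <= 5
            assert hit.tsd == t.tsd
            assert hit.motif_ok
    assert found >= 0.95 * len(elements)


def test_every_candidate_satisfies_param_windows(small_genome):
    _, genome, _ = small_genome
    params = LTRParams()
    for c in find_ltr_candidates(genome, params):
        assert params.min_ltr_len <= c.ltr_len <= params.max_ltr_len
        dist = c.ltr3[0] - c.ltr5[0]
        assert params.min_ltr_dist <= dist <= params.max_ltr_dist
        assert c.ltr_identity >= params.min_similarity


def test_diverged_element_moves_from_recent_to_ancient_scan():
    """An element aged to ~85% LTR identity fails the 90% scan but is
    collected by the 75% scan."""
    # p = 0.15 => d = JC(p), age = d/(2 mu)
    d = -0.75 * math.log(1 - 4 * 0.15 / 3)
    age = d / (2 * 6.5e-9)
    cfg = SimConfig(
        seed=31, genome_len=250_000, n_elements=4, age_range=(age, age),
        ltr_len_range=(1000, 1000), internal_len_range=(2500, 2500),
        nest_prob=0.0, gap_prob=0.0, decoy_count=0, n_element_families=1,
    )
    genome, truth = simulate_ltr_genome(cfg)
    recent = find_ltr_candidates(genome, LTRParams())
    ancient_params = LTRParams().relaxed_for_ancient()
    permissive = find_ltr_candidates(genome, ancient_params)
    assert len(recent) == 0
    assert len(permissive) >= 3
    assert all(75 <= c.ltr_identity < 92 for c in permissive)


def test_short_direct_repeats_below_min_ltr_len_are_ignored():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    bg = "".join(rng.choice(bases, 6000))
    rep = "TG" + "".join(rng.choice(bases, 76)) + "CA"  # 80 bp < 100
    tsd = "ACGTA"
    seq = bg[:2000] + tsd + rep + bg[2000:4000] + rep + tsd + bg[4000:]
    assert find_ltr_candidates({"c": seq}, LTRParams()) == []


def test_element_free_random_sequence_yields_nothing():
    cfg = SimConfig(seed=37, genome_len=500_000, n_elements=0, decoy_count=0)
    genome, _ = simulate_ltr_genome(cfg)
    assert find_ltr_candidates(genome, LTRParams()) == []


# ---------------------------------------------------------------------------
# filters


@pytest.fixture(scope="module")
def filtered_run():
    cfg = SimConfig(
        seed=41, genome_len=700_000, n_elements=25, age_range=(0.0, 3.0e6),
        nest_prob=0.3, gap_prob=0.15, decoy_count=4, n_element_families=2,
    )
    genome, truth = simulate_ltr_genome(cfg)
    params = LTRParams().relaxed_for_ancient()
    cands = find_ltr_candidates(genome, params)
    kept, rejected = filter_candidates(cands, genome)
    return cfg, genome, truth, cands, kept, rejected


def test_gappy_elements_rejected_with_reason(filtered_run):
    _, _, truth, _, kept, rejected = filtered_run
    gappy_truth = [t for t in truth.element_truth.values() if t.gappy]
    gappy_rej = [r for r in rejected if r.reason == "gappy"]
    assert len(gappy_rej) == len(gappy_truth) > 0
    for r in gappy_rej:
        assert any(_match(r.element, t) for t in gappy_truth)


def test_tandem_decoys_rejected_as_alignable_flanks(filtered_run):
    _, _, truth, _, kept, rejected = filtered_run
    decoys = [t for t in truth.element_truth.values() if t.kind == "decoy"]
    flank_rej = [r for r in rejected if r.reason == "alignable_flanks"]
    assert len(flank_rej) == len(decoys) > 0
    for r in flank_rej:
        assert any(_match(r.element, t) for t in decoys)


def test_nested_pairs_kept_with_outer_excision_matching_truth(filtered_run):
    _, _, truth, _, kept, _ = filtered_run
    tr = truth.element_truth
    # nested pairs where neither member is gap-corrupted (those are
    # legitimately removed by the gappy filter)
    clean_nested = [
        t for t in tr.values()
        if t.nested_in and not t.gappy and not tr[t.nested_in].gappy
    ]
    assert clean_nested
    outers = [e for e in kept if "nested" in e.flags]
    for t in clean_nested:
        inner = next(e for e in kept if _match(e, t))
        host = next(e for e in outers if e.internal[0] <= inner.start <= e.internal[1])
        assert host.excised == (inner.start, inner.end + len(inner.tsd))
        assert _match(host, tr[t.nested_in])


# ---------------------------------------------------------------------------
# classification and exemplars


def test_classification_thresholds(small_genome):
    _, genome, _ = small_genome
    params = LTRParams()
    cands = find_ltr_candidates(genome, params.relaxed_for_ancient())
    kept, _ = filter_candidates(cands, genome)
    recent, ancient, lib = classify_age_class(kept, genome, params)
    for el in recent:
        assert el.ltr_identity >= 90 and el.motif_ok
    for el in ancient:
        assert 75 <= el.ltr_identity < 90


def test_identical_elements_cluster_to_one_exemplar(small_genome):
    _, genome, _ = small_genome
    cands = find_ltr_candidates(genome, LTRParams())
    kept, _ = filter_candidates(cands, genome)
    lib = build_exemplars(kept, genome)
    # two planted families -> two internal-basis exemplars
    internal = [x for x in lib.exemplars if x.basis == "internal"]
    assert len(internal) == 2
    assert sum(len(x.members) for x in internal) == len(kept)


def test_empty_element_list_gives_empty_library():
    lib = build_exemplars([], {"c": "ACGT"})
    assert lib.exemplars == []


# ---------------------------------------------------------------------------
# dating


def test_jc_age_known_arithmetic():
    """1,000-site alignment with 100 mismatches: d = -(3/4) ln(1-0.4/3)
    = 0.107326, T = d / (2 x 6.5e-9) = 8.256e6 years."""
    d, T = jc_age(0.1)
    assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
    assert d == pytest.approx(0.1073256, abs=1e-6)
    assert T == pytest.approx(d / (2 * 6.5e-9), rel=1e-12)
    assert T == pytest.approx(8.2558e6, rel=1e-4)


def test_identical_ltrs_date_to_zero(small_genome):
    _, genome, _ = small_genome
    el = LTRElement("e0", "chr1", (100, 200), (1700, 1800))
    # fabricate identical repeats inside a copy of the genome
    seq = genome["chr1"]
    g = {"chr1": seq[:100] + seq[100:200] + seq[200:1700] + seq[100:200] + seq[1800:]}
    ages = date_insertions([el], g, strict=False)
    assert ages[0].p == 0.0 and ages[0].d == 0.0 and ages[0].T == 0.0


def test_saturated_ltr_pair_is_flagged():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACGT"), 400))
    b = "".join(rng.choice(list("TGCA"), 400))
    g = {"c": a + "X" * 0 + b}
    el = LTRElement("e0", "c", (0, 400), (400, 800))
    ages = date_insertions([el], g, strict=False)
    assert ages[0].saturated or ages[0].p < 0.75  # random ~0.75; either flagged or just below
    if ages[0].saturated:
        assert ages[0].T is None


def test_age_is_linear_in_inverse_rate(small_genome):
    _, genome, truth = small_genome
    cands = find_ltr_candidates(genome, LTRParams())
    kept, _ = filter_candidates(cands, genome)
    recent, _, _ = classify_age_class(kept, genome, LTRParams())
    a1 = date_insertions(recent, genome, mu=6.5e-9)
    a2 = date_insertions(recent, genome, mu=1.3e-8)
    for x, y in zip(a1, a2):
        if x.T and y.T:
            assert x.T == pytest.approx(2 * y.T, rel=1e-9)


def test_planted_ages_recovered(small_genome):
    cfg, genome, truth = small_genome
    res = run_ltr(genome)
    errs = []
    for a in res.ages:
        el = next(e for e in res.recent if e.element_id == a.element_id)
        t = next(
            (t for t in truth.element_truth.values() if _match(el, t, tol=10)), None
        )
        if t is not None and t.age_years > 1e5 and a.T is not None:
            errs.append(abs(a.T - t.age_years) / t.age_years)
    assert errs
    assert float(np.median(errs)) < 0.10


# ---------------------------------------------------------------------------
# masking and summary


def test_masking_covers_planted_elements(small_genome):
    _, genome, truth = small_genome
    res = run_ltr(genome)
    masked = res.masked["chr1"]
    assert len(masked) == len(genome["chr1"])
    planted = [
        (t.start, t.end) for t in truth.element_truth.values() if t.kind == "element"
    ]
    covered = total = 0
    for lo, hi in planted:
        total += hi - lo
        covered += sum(1 for c in masked[lo:hi] if c.islower())
    assert covered / total >= 0.99
    # uppercase preserved elsewhere: unmasked content identical
    assert masked.upper() == genome["chr1"].upper()


def test_empty_library_masks_nothing(small_genome):
    _, genome, _ = small_genome
    from ploidyscape.ltr.library import ExemplarLibrary

    masked, ann = mask_genome(genome, ExemplarLibrary(80.0, 90.0))
    assert masked == genome and ann == []


def test_masking_is_idempotent(small_genome):
    _, genome, _ = small_genome
    cands = find_ltr_candidates(genome, LTRParams())
    kept, _ = filter_candidates(cands, genome)
    lib = build_exemplars(kept, genome)
    once, _ = mask_genome(genome, lib)
    twice, _ = mask_genome(once, lib)
    assert once == twice


def test_summary_arithmetic():
    ann = [
        {"contig": "c", "start": 0, "end": 30_000, "label": "LTR/unknown"},
        {"contig": "c", "start": 20_000, "end": 42_000, "label": "LTR/unknown"},
    ]
    rows = summarize_repeats(ann, 100_000)
    by = {r.label: r for r in rows}
    assert by["LTR/unknown"].total_bp == 42_000  # overlap merged
    assert by["LTR/unknown"].pct_genome == pytest.approx(42.0)
    assert by["unmasked"].pct_genome == pytest.approx(58.0)
    assert sum(r.pct_genome for r in rows) == pytest.approx(100.0, abs=0.01)


def test_empty_annotation_gives_full_remainder():
    rows = summarize_repeats([], 50_000)
    assert len(rows) == 1
    assert rows[0].label == "unmasked" and rows[0].pct_genome == pytest.approx(100.0)
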