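"""Synthetic-data generators: determinism, truth conservation, and
statistical fidelity of the planted signals."""

import math

import numpy as np
import pytest

from ploidyscape.ksdist import estimate_pair_ks
from ploidyscape.synthdata import (
    SimConfig,
    simulate_gene_families,
    simulate_gene_trees,
    simulate_ltr_genome,
)


# ---------------------------------------------------------------------------
# gene families


def test_zero_families_give_empty_outputs():
    cfg = SimConfig(seed=0, n_families=0)
    coding, proteins, truth = simulate_gene_families(cfg)
    assert coding == {} and proteins == {} and truth.paralog_truth == {}


def test_same_seed_reproduces_identical_families():
    a = simulate_gene_families(SimConfig(seed=5, n_families=30))
    b = simulate_gene_families(SimConfig(seed=5, n_families=30))
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].paralog_truth == b[2].paralog_truth


def test_every_truth_pair_exists_in_fasta(small_families):
    _, coding, proteins, truth = small_families
    for a, b in truth.paralog_truth:
        assert a in coding and b in coding
        assert len(coding[a]) % 3 == 0
        assert len(proteins[a]) * 3 == len(coding[a])


def test_no_internal_stops_in_generated_proteins(small_families):
    _, _, proteins, _ = small_families
    assert not any("*" in p for p in proteins.values())


def test_wgd_pairs_recover_planted_ks(small_families):
    """Mean NG86+JC Ks over truth-labeled WGD pairs sits within 0.05
    of the planted divergence (the generator's core contract)."""
    cfg, coding, proteins, truth = small_families
    ks = [
        estimate_pair_ks(a, b, coding, proteins).Ks
        for (a, b), (k, origin) in truth.paralog_truth.items()
        if origin == "wgd"
    ]
    assert len(ks) > 20
    assert abs(float(np.mean(ks)) - cfg.wgd_ks) < 0.05


def test_background_pairs_recover_their_own_divergences(small_families):
    cfg, coding, proteins, truth = small_families
    errs = []
    for (a, b), (k, origin) in truth.paralog_truth.items():
        if origin != "background" or k > 1.5:
            continue
        est = estimate_pair_ks(a, b, coding, proteins)
        if est.Ks is not None:
            errs.append(est.Ks - k)
    assert len(errs) > 10
    assert abs(float(np.mean(errs))) < 0.08


def test_invalid_probability_rejected():
    with pytest.raises(ValueError, match="wgd_retention"):
        SimConfig(wgd_retention=1.5).validate()


# ---------------------------------------------------------------------------
# gene trees


def test_zero_probability_trees_copy_the_species_tree(species_tree):
    trees, truth = simulate_gene_trees(species_tree, 5, {}, seed=1)
    assert len(set(trees)) == 1  # same topology, same labels
    assert all(not ev for ev in truth.tree_truth.values())


def test_forced_duplication_in_every_tree(species_tree):
    trees, truth = simulate_gene_trees(
        species_tree, 10, {"Azolla+Ceratopteris": 1.0}, seed=2
    )
    assert all("Ceratopteris|g1" in t and "Azolla|g1" in t for t in trees)
    assert all(ev == [("Azolla+Ceratopteris", 1)] for ev in truth.tree_truth.values())


def test_duplication_rate_matches_binomial_sampling(species_tree):
    p, n = 0.34, 2000
    trees, truth = simulate_gene_trees(
        species_tree, n, {"Azolla+Ceratopteris": p}, seed=3
    )
    frac = sum(1 for ev in truth.tree_truth.values() if ev) / n
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_tree_determinism(species_tree):
    a, _ = simulate_gene_trees(species_tree, 20, {"Azolla+Ceratopteris": 0.4}, seed=9)
    b, _ = simulate_gene_trees(species_tree, 20, {"Azolla+Ceratopteris": 0.4}, seed=9)
    assert a == b


# ---------------------------------------------------------------------------
# LTR genome


def test_zero_age_elements_have_identical_ltrs():
    cfg = SimConfig(
        seed=11, genome_len=200_000, n_elements=5, age_range=(0.0, 0.0),
        nest_prob=0.0, gap_prob=0.0, decoy_count=0,
    )
    genome, truth = simulate_ltr_genome(cfg)
    seq = genome["chr1"]
    for t in truth.element_truth.values():
        ltr5 = seq[t.ltr5[0] : t.ltr5[1]]
        ltr3 = seq[t.ltr3[0] : t.ltr3[1]]
        assert ltr5 == ltr3
        assert ltr5.startswith("TG") and ltr5.endswith("CA")
        # target-site duplication flanks the element
        assert seq[t.start - 5 : t.start] == seq[t.end : t.end + 5] == t.tsd


def test_genome_determinism():
    cfg = SimConfig(seed=13, genome_len=150_000, n_elements=4)
    g1, t1 = simulate_ltr_genome(cfg)
    g2, t2 = simulate_ltr_genome(cfg)
    assert g1 == g2
    assert t1.element_gff_rows() == t2.element_gff_rows()


def test_aged_ltr_divergence_follows_jukes_cantor():
    """Planted 8-My elements at 6.5e-9/site/yr: the LTR-pair mismatch
    proportion must sit at the JC expectation for d = 2 x age x rate
    within Monte-Carlo error."""
    age, rate = 8.0e6, 6.5e-9
    cfg = SimConfig(
        seed=17, genome_len=400_000, n_elements=12, age_range=(age, age),
        ltr_len_range=(1000, 1000), internal_len_range=(2000, 2000),
        nest_prob=0.0, gap_prob=0.0, decoy_count=0, n_element_families=3,
    )
    genome, truth = simulate_ltr_genome(cfg)
    seq = genome["chr1"]
    d = 2 * age * rate
    p_expect = 0.75 * (1 - math.exp(-4 * d / 3))
    ps = []
    for t in truth.element_truth.values():
        a = seq[t.ltr5[0] : t.ltr5[1]]
        b = seq[t.ltr3[0] : t.ltr3[1]]
        ps.append(sum(x != y for x, y in zip(a, b)) / len(a))
    mean_p = float(np.mean(ps))
    # per-element MC sd ~ sqrt(p/L); the mean over 12 elements tightens it
    assert abs(mean_p - p_expect) < 3 * math.sqrt(p_expect / 1000 / len(ps)) + 2e-3


def test_gap_prob_one_corrupts_every_element_body():
    cfg = SimConfig(
        seed=19, genome_len=300_000, n_elements=8, gap_prob=1.0,
        nest_prob=0.0, decoy_count=0,
    )
    genome, truth = simulate_ltr_genome(cfg)
    seq = genome["chr1"]
    for t in truth.element_truth.values():
        body = seq[t.start : t.end]
        assert "N" * 51 in body
        assert t.gappy


def test_nested_elements_sit_inside_host_internal_regions():
    cfg = SimConfig(seed=23, genome_len=600_000, n_elements=25, nest_prob=0.6,
                    gap_prob=0.0, decoy_count=0)
    genome, truth = simulate_ltr_genome(cfg)
    nested = [t for t in truth.element_truth.values() if t.nested_in]
    assert nested, "nesting probability 0.6 over 25 elements must nest some"
    for t in nested:
        host = truth.element_truth[t.nested_in]
        assert host.ltr5[1] <= t.start and t.end <= host.ltr3[0]
        assert t.age_years <= host.age_years


def test_truth_row_count_matches_planted_objects():
    cfg = SimConfig(seed=29, genome_len=400_000, n_elements=10, decoy_count=3)
    _, truth = simulate_ltr_genome(cfg)
    kinds = [t.kind for t in truth.element_truth.values()]
    assert kinds.count("element") == 10
    assert kinds.count("decoy") == 3


def test_infeasible_packing_raises():
    cfg = SimConfig(seed=1, genome_len=30_000, n_elements=10)
    with pytest.raises(ValueError, match="infeasible packing"):
        simulate_ltr_genome(cfg)


def test_spacing_window_validation():
    with pytest.raises(ValueError, match="spacing"):
        SimConfig(ltr_len_range=(100, 200), internal_len_range=(100, 400)).validate()
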