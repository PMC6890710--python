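"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from ploidyscape.pipeline import default_species_tree
from ploidyscape.synthdata import SimConfig, simulate_gene_families, simulate_ltr_genome


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def small_families():
    """120 families with a WGD burst at Ks = 0.8."""
    cfg = SimConfig(seed=42, n_families=120, wgd_ks=0.8, wgd_retention=0.4)
    coding, proteins, truth = simulate_gene_families(cfg)
    return cfg, coding, proteins, truth


@pytest.fixture(scope="session")
def small_genome():
    """300-kb genome with 12 clean planted elements (no decoys/gaps)."""
    cfg = SimConfig(
        seed=7,
        genome_len=300_000,
        n_elements=12,
        age_range=(0.0, 2.0e6),
        nest_prob=0.0,
        gap_prob=0.0,
        decoy_count=0,
        n_element_families=2,
    )
    genome, truth = simulate_ltr_genome(cfg)
    return cfg, genome, truth


# the standard genetic code, hard-coded independently of the
# implementation (which reads it from Bio.Data.CodonTable)
_CODE_TEXT = """
TTT:F TTC:F TTA:L TTG:L CTT:L CTC:L CTA:L CTG:L
ATT:I ATC:I ATA:I ATG:M GTT:V GTC:V GTA:V GTG:V
TCT:S TCC:S TCA:S TCG:S CCT:P CCC:P CCA:P CCG:P
ACT:T ACC:T ACA:T ACG:T GCT:A GCC:A GCA:A GCG:A
TAT:Y TAC:Y TAA:* TAG:* CAT:H CAC:H CAA:Q CAG:Q
AAT:N AAC:N AAA:K AAG:K GAT:D GAC:D GAA:E GAG:E
TGT:C TGC:C TGA:* TGG:W CGT:R CGC:R CGA:R CGG:R
AGT:S AGC:S AGA:R AGG:R GGT:G GGC:G GGA:G GGG:G
"""

ORACLE_CODE = dict(
    pair.split(":") for pair in _CODE_TEXT.split()
)


@pytest.fixture(scope="session")
def oracle_code():
    return ORACLE_CODE
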