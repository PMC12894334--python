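import numpy as np
import pytest

from plastocodon.simulate import SyntheticGenomeSpec, make_plastome

MIXED_SSRS = [
    ("A", 12, "IGS"),
    ("T", 11, "IGS"),
    ("AT", 6, "IGS"),
    ("AG", 5, "IGS"),
    ("AAT", 5, "IGS"),
    ("ACC", 4, "IGS"),
    ("AAAT", 4, "IGS"),
    ("AATG", 3, "intron"),
    ("AACAG", 3, "intron"),
    ("AACGAC", 3, "IGS"),
    ("A", 10, "CDS"),
    ("AGGC", 4, "CDS"),
]


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticGenomeSpec(
        seed=7,
        lsc_len=9000,
        ssc_len=1600,
        ir_len=2500,
        n_genes=8,
        gene_length_codons=120,
        planted_ssrs=list(MIXED_SSRS),
        genome_id="SYN001",
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    """One 15.6 kb synthetic plastome with 12 planted SSRs + truth table."""
    return make_plastome(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
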