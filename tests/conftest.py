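import pytest

from maexp.simulate import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """150 kb synthetic genome at study-like composition."""
    return generate_genome(GenomeSpec(length=150_000, seed=101))


@pytest.fixture(scope="session")
def study_genome():
    """Genome sized to the mean callable fraction of the study (3.5 Mb)."""
    return generate_genome(GenomeSpec(length=3_500_000, seed=7))


@pytest.fixture(scope="session")
def tiny_genome():
    """Small multi-CDS genome for exhaustive coding-effect enumeration."""
    return generate_genome(
        GenomeSpec(length=9_000, coding_fraction=0.8, ssr_target_fraction=0.01, seed=23, mean_gene_codons=60)
    )
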