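import pytest

from mitocomp import Feature, MitoGenome
from mitocomp.synthetic import demo_genome_spec, generate_genome


@pytest.fixture
def tiny_genome() -> MitoGenome:
    """60 bp with one CDS(+) and one tRNA(-), deliberately given unsorted."""
    #        1         11        21        31        41        51
    seq = "AACCATGAAATTTGGGTAAACCTTAACCGGTTAACCGGTTCCAATTGGCCAATTGGCCAA"
    return MitoGenome(
        "tiny", seq, circular=True,
        features=[
            Feature("trnF", "tRNA", 41, 60, "-"),
            Feature("cox1", "CDS", 5, 19, "+"),
        ])


@pytest.fixture(scope="session")
def demo_genome():
    """17,197 bp AT-rich synthetic genome with 3 embedded SSRs (seed 11)."""
    return generate_genome(demo_genome_spec(11))
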