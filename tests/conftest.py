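import pytest

from bcoritd.fixtures import bcor_like_locus
from bcoritd.locus import AlleleSpec, CdnaInterval
from bcoritd.simulate import SimulationConfig, make_reference, simulate_reads
from bcoritd.align import align_pairs


@pytest.fixture(scope="session")
def bcor():
    """The synthetic BCOR-like minus-strand fixture locus."""
    return bcor_like_locus()


@pytest.fixture(scope="session")
def small_locus():
    """A random ~1.1 kb single-exon minus-strand locus."""
    return make_reference(42)


@pytest.fixture(scope="session")
def type1_sample(small_locus):
    """Aligned records for a hemizygous pure-mutant 96-bp clean ITD."""
    allele = AlleleSpec(dup=CdnaInterval(500, 595))
    cfg = SimulationConfig(
        seed=7, coverage=100, mutant_fraction=1.0, sample_state="hemizygous"
    )
    pairs, truth = simulate_reads(small_locus, allele, cfg)
    records = [
        rec
        for pair in align_pairs(pairs, small_locus.transcript_seq, small_locus.name)
        for rec in pair
    ]
    return allele, records, truth


@pytest.fixture(scope="session")
def itd_free_sample(small_locus):
    """Aligned records for a wild-type-only sample (error rate 0.005)."""
    cfg = SimulationConfig(seed=8, coverage=100, error_rate=0.005)
    pairs, _ = simulate_reads(small_locus, AlleleSpec(), cfg)
    return [
        rec
        for pair in align_pairs(pairs, small_locus.transcript_seq, small_locus.name)
        for rec in pair
    ]
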