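import numpy as np
import pytest

from b2proc import (
    GenomicInterval,
    ReadAlignment,
    RepeatLocus,
    simulate_repeat_loci,
)
from b2proc.core import make_locus_id


def make_locus(chrom="chr1", start=100, end=288, strand="+", subfamily="B2_Mm2"):
    iv = GenomicInterval(chrom, start, end, strand)
    return RepeatLocus(iv, subfamily, make_locus_id(iv))


def make_read(chrom="chr1", start=0, end=30, strand="+", read_id="r", library="short",
              is_primary=True):
    return ReadAlignment(read_id, GenomicInterval(chrom, start, end, strand), strand,
                         is_primary=is_primary, library=library)


@pytest.fixture(scope="session")
def genome():
    """Shared small toy genome (30 B2 copies, 20 tRNAs)."""
    return simulate_repeat_loci(30, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
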