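import numpy as np
import pytest

from svkit.records import Breakpoint, SVRecord
from svkit.simulate import SimCohort, make_toy_genome


@pytest.fixture(scope="session")
def genome():
    return make_toy_genome()


@pytest.fixture
def cohort(genome):
    return SimCohort(genome=genome)


def make_sv(id, c1, p1, o1, c2, p2, o2, sample="S1", mh=0, ins=0, qual=10.0):
    return SVRecord(
        id=id,
        bp1=Breakpoint(c1, p1, o1),
        bp2=Breakpoint(c2, p2, o2),
        mh_len=mh,
        ins_len=ins,
        qual=qual,
        sample=sample,
    )


@pytest.fixture
def flat_track():
    """Constant 1.0 coverage over three 50 Mb chromosomes."""
    from svkit.records import CoverageTrack

    t = CoverageTrack(bin_size=10_000, sample="S1")
    for c in ("chr1", "chr2", "chr3"):
        t.add_chrom(c, 0, np.ones(5000))
    return t
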