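import numpy as np
import pytest

from selandscape.genomic import GenomicInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_interval(chrom="chr1", start=0, end=100):
    return GenomicInterval(chrom, start, end)


def make_peak(chrom="chr1", start=0, end=100, name=".", score=0.0):
    return Peak(GenomicInterval(chrom, start, end), name=name, score=score)


@pytest.fixture
def random_regions(rng):
    """Non-degenerate random intervals on two chromosomes."""

    def _make(n, max_pos=10_000, chroms=("chr1", "chr2")):
        out = []
        for _ in range(n):
            chrom = chroms[rng.integers(0, len(chroms))]
            s = int(rng.integers(0, max_pos - 1))
            e = int(rng.integers(s + 1, min(s + 500, max_pos)))
            out.append(GenomicInterval(chrom, s, e))
        return out

    return _make
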