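import numpy as np
import pytest

from ectoreg.formats_io import GenomicInterval


def iv(chrom, start, end, **kwargs):
    return GenomicInterval(chrom, start, end, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_peak_set(rng, chrom="c", length=10_000, max_peaks=5):
    """Random small peak set for oracle comparisons."""
    n = int(rng.integers(0, max_peaks + 1))
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, length - 2))
        end = int(rng.integers(start + 1, min(start + 1 + 2_000, length)))
        peaks.append(GenomicInterval(chrom, start, end))
    return peaks


def coverage_bitmap(peaks, length=10_000):
    cov = np.zeros(length, dtype=bool)
    for p in peaks:
        cov[p.start:p.end] = True
    return cov


def ranking_from_signals(signals):
    """EnhancerRanking over dummy loci carrying the given sorted signals."""
    from ectoreg.setools import EnhancerRanking, StitchedEnhancer

    ordered = sorted(signals)
    loci = [
        StitchedEnhancer(GenomicInterval("c", 10 * i, 10 * i + 5), [i],
                         float(s), i)
        for i, s in enumerate(ordered)
    ]
    return EnhancerRanking(loci, np.array(ordered, dtype=float))
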