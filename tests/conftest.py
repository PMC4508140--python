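import numpy as np
import pytest

from cerna_scan.models import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_transcript(
    tid: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    biotype: str = "lncRNA",
    gene_name: str | None = None,
) -> TranscriptModel:
    """Concise transcript builder for geometry tests."""
    intervals = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    locus = GenomicInterval(chrom, intervals[0].start, intervals[-1].end, strand)
    return TranscriptModel(tid, gene_name or tid, biotype, locus, intervals)


@pytest.fixture
def transcript_factory():
    return make_transcript
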