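import numpy as np
import pytest

from utrterm.formats_io import GenomeInterval
from utrterm.transcript_model import TranscriptAnnotation


def make_annotation(
    tid="t1",
    gene=None,
    chrom="chr1",
    strand="+",
    utr5=50,
    cds=300,
    utr3=200,
    utr3_start=1000,
    sequence=None,
):
    iv = GenomeInterval(chrom, utr3_start, utr3_start + utr3, strand) if utr3 else None
    return TranscriptAnnotation(
        transcript_id=tid,
        gene_id=gene or tid.replace("t", "g"),
        chrom=chrom,
        strand=strand,
        utr5_len=utr5,
        cds_len=cds,
        utr3_len=utr3,
        utr3_interval=iv,
        sequence=sequence,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_utr():
    """A '+' strand transcript with a 200 nt 3'-UTR at chr1:1000-1200."""
    return make_annotation()


@pytest.fixture
def minus_utr():
    return make_annotation(tid="t2", strand="-", utr3_start=2000)
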