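import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scaprna.core import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_transcript(tid="tx1", gid="gene1", biotype="mRNA", chrom="chr1",
                    strand="+", blocks=((1000, 1100), (1500, 1650))):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
    return TranscriptModel(tid, gid, biotype, exons)


@pytest.fixture
def two_exon_tx():
    return make_transcript()
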