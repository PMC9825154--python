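import pytest

from tcpseq import GeneratorParams, make_transcriptome
from tcpseq.annotation import TranscriptModel
from tcpseq.preprocess import ExactIndex


@pytest.fixture(scope="session")
def params():
    return GeneratorParams(seed=1, n_genes=8)


@pytest.fixture(scope="session")
def sim(params):
    """(models, uorfs, rrna) for the default synthetic transcriptome."""
    return make_transcriptome(params)


@pytest.fixture(scope="session")
def models(sim):
    return sim[0]


@pytest.fixture(scope="session")
def rrna(sim):
    return sim[2]


@pytest.fixture(scope="session")
def index(models):
    return ExactIndex(models)


@pytest.fixture
def toy_model():
    """100 nt extension + 20 nt 5'UTR + 9 nt CDS + 4 nt 3'UTR (length 133)."""
    return TranscriptModel(
        id="toy",
        sequence="A" * 100 + "ACGT" * 5 + "ATGAAATGA" + "TTTT",
        ext_len=100,
        utr5_len=20,
        cds_len=9,
        utr3_len=4,
    )
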