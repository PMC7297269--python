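import logging

import numpy as np
import pytest

from lncm6a.simulate import FixtureConfig, generate_fixture
from lncm6a.transcripts import TranscriptModel

logging.getLogger("lncm6a").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_fixture():
    """Small planted-signal fixture shared across tests (seeded)."""
    cfg = FixtureConfig(seed=424242, n_lnc_genes=20, n_mrna_genes=20,
                        n_positives_lnc=120, n_positives_mrna=120)
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def noiseless_fixture():
    cfg = FixtureConfig(seed=99, n_lnc_genes=12, n_mrna_genes=12,
                        n_positives_lnc=60, n_positives_mrna=60,
                        dropout=0.0, false_call_rate=0.0)
    return generate_fixture(cfg)


@pytest.fixture
def two_exon_plus():
    """Plus-strand transcript, exons [1,100] and [201,300] (mature 200 nt)."""
    return TranscriptModel("txA", "geneA", "chr1", "+", [(1, 100), (201, 300)])


@pytest.fixture
def three_exon_minus():
    return TranscriptModel("txB", "geneB", "chr1", "-",
                           [(100, 199), (300, 349), (500, 599)])


@pytest.fixture
def rng():
    return np.random.default_rng(20200609)
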