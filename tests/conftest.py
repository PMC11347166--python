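import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ribodwell import synthio
from ribodwell.transcripts import TranscriptSet


@pytest.fixture(scope="session")
def toy_tx() -> TranscriptSet:
    """Five transcripts of 80 codons — small enough for brute-force oracles."""
    return synthio.gen_transcriptome(5, 80, seed=101)


@pytest.fixture(scope="session")
def mid_tx() -> TranscriptSet:
    return synthio.gen_transcriptome(100, 120, seed=7)


@pytest.fixture(scope="session")
def rpf_design() -> synthio.DesignTable:
    return synthio.standard_design(assays=("RPF",))


@pytest.fixture(scope="session")
def full_design() -> synthio.DesignTable:
    return synthio.standard_design(ko_clones=("k1",), assays=("RPF", "RNA"))


@pytest.fixture(scope="session")
def uniform_model() -> synthio.DwellModel:
    return synthio.DwellModel.uniform(depth=2e5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
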