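import numpy as np
import pytest

from plangpcr.io_formats import SequenceRecord
from plangpcr.synthetic import make_transcriptome


@pytest.fixture(scope="session")
def transcriptome():
    """Default planted transcriptome (12 receptors, 8 decoys, 50 background)."""
    records, seeds, truth = make_transcriptome(seed=11)
    return records, seeds, truth


@pytest.fixture
def rng():
    return np.random.RandomState(1234)


@pytest.fixture
def receptor_protein():
    """A synthetic 7TM protein with planted segment positions."""
    from plangpcr.synthetic import _receptor_architecture

    r = np.random.RandomState(7)
    seq, _, segs = _receptor_architecture(r)
    return SequenceRecord("rec7tm", seq, "protein"), segs
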