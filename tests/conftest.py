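import numpy as np
import pytest

from rlfm.construct import SequenceBatch, build_batch_bwt


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ds_index_worked_example():
    """Double-strand index of the single reference string GACCTCCG."""
    return build_batch_bwt(SequenceBatch(["GACCTCCG"], double_strand=True))
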