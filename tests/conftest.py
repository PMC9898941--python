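import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230204)


@pytest.fixture
def bipolar_reads():
    """20 all-unmethylated plus 20 all-methylated reads on a 4-CpG segment."""
    from mentropy import ReadMatrix

    x = np.vstack([np.zeros((20, 4), dtype=int), np.ones((20, 4), dtype=int)])
    return ReadMatrix(x)
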