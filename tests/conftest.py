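import numpy as np
import pytest

from lrcomm.lr_database import LRPair, LRDatabase


@pytest.fixture
def tiny_db() -> LRDatabase:
    return LRDatabase(
        pairs=(
            LRPair("LGALS9", "HAVCR2"),
            LRPair("CXCL12", "CXCR4"),
            LRPair("LGALS9", "SORL1"),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
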