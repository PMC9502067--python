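import numpy as np
import pytest

from poolscape.io_formats import SyncRecord
from poolscape.poolfreq import FilterConfig


@pytest.fixture
def filter_cfg() -> FilterConfig:
    return FilterConfig()


def make_record(chrom="chr1", pos=100, ref="A", pools=None) -> SyncRecord:
    if pools is None:
        pools = ((90, 10, 0, 0, 0, 0), (50, 50, 0, 0, 0, 0))
    return SyncRecord(chrom, pos, ref, tuple(tuple(p) for p in pools))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
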