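import numpy as np
import pytest

from scmirna import preprocess as pp
from scmirna import simulate as sim


@pytest.fixture(scope="session")
def refs_small():
    """50 synthetic short-RNA references, fixed seed."""
    return sim.generate_reference(50, seed=7)


@pytest.fixture(scope="session")
def refs_pool():
    """Full-size (1006-sequence) equimolar-pool stand-in, fixed seed."""
    return sim.generate_reference(1006, seed=7)


@pytest.fixture(scope="session")
def arch():
    return sim.ProtocolArchitecture()


@pytest.fixture(scope="session")
def trim_cfg():
    return pp.TrimConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_read(seq, quals=None, read_id="r1", umi=""):
    from scmirna.refio import SmallRNARecord

    if quals is None:
        quals = [37] * len(seq)
    return SmallRNARecord(read_id=read_id, sequence=seq, qualities=quals, umi=umi)
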