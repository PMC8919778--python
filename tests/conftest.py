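import numpy as np
import pytest

from g2i.hits import DomainHit
from g2i.synth import parts_library


@pytest.fixture(scope="session")
def parts():
    return parts_library()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def mk_hit(
    kind="RT",
    start=0,
    end=100,
    strand="+",
    bits=100.0,
    evalue=1e-50,
    cov=1.0,
    qid="q1",
    replicon="chr1",
    iep_type=None,
    source="alignment",
):
    return DomainHit(
        replicon_id=replicon,
        kind=kind,
        start=start,
        end=end,
        strand=strand,
        bit_score=bits,
        evalue=evalue,
        query_id=qid,
        query_coverage=cov,
        iep_type=iep_type,
        source=source,
    )


@pytest.fixture
def hit_factory():
    return mk_hit
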