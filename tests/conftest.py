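import pytest

from sncrna import synthetic as syn
from sncrna.mirna import MirnaRef
from sncrna.synthetic import to_readset


@pytest.fixture(scope="session")
def hairpin_refs():
    return syn.gen_hairpin_refs(10, seed=11)


@pytest.fixture(scope="session")
def mirna_ref(hairpin_refs):
    return MirnaRef.from_records(hairpin_refs)


@pytest.fixture(scope="session")
def mirna_grid(hairpin_refs):
    return syn.gen_mirna_testset(hairpin_refs, seed=11)


@pytest.fixture(scope="session")
def trna_refs():
    return syn.gen_trna_refs(8, seed=12)


@pytest.fixture(scope="session")
def trf_set(trna_refs):
    return syn.gen_trf_testset(trna_refs, seed=12)


@pytest.fixture
def readset_of():
    def _make(*pairs):
        from sncrna.core import ReadSet

        return ReadSet.from_iter(pairs)

    return _make
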