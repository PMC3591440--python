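import pytest

from frdsig.core import Msa, ProteinRecord
from frdsig.refmap import load_nox2_reference


@pytest.fixture(scope="session")
def nox2():
    """The bundled human NOX2 reference annotation."""
    return load_nox2_reference()


def make_msa(rows, ids=None):
    """Build an Msa from raw row strings."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Msa([ProteinRecord(id=i, sequence=r) for i, r in zip(ids, rows)])


@pytest.fixture
def msa_factory():
    return make_msa
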