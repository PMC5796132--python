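import numpy as np
import pytest

from funcbench.features import groupings
from funcbench.records import ProteinRecord
from funcbench.simulate import FamilySpec, generate_family, generate_negative_pool

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def charge():
    (g,) = [g for g in groupings() if g.property_name == "charge"]
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_family():
    return generate_family(FamilySpec("FAMX", n_members=12, seed=11))


@pytest.fixture(scope="session")
def small_pool():
    return generate_negative_pool(6, group_size_range=(3, 5), seed=12)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def make_records():
    def _make(seqs, prefix="r"):
        return [ProteinRecord(id=f"{prefix}{i}", sequence=s) for i, s in enumerate(seqs)]

    return _make
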