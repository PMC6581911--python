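import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capri.adjacency import ProteinRecord
from capri.ptm_catalog import build_catalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return build_catalog(max_nt=3, include_cyclic=True)


@pytest.fixture(scope="session")
def catalog_by_name(catalog):
    return {d.name: d for d in catalog}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_protein():
    return ProteinRecord("P1", "MKALPVRGGSKQ", gene_id="g1")


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))
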