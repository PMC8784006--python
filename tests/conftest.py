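import numpy as np
import pytest

from dhnsurvey.datasets import load_table1


@pytest.fixture(scope="session")
def table1():
    """The bundled 117-gene published survey table."""
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def random_cds(rng, n_codons: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"
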