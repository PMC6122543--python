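import numpy as np
import pytest

from madswalk.pipeline import build_profiles
from madswalk.synthetic_data import gen_gene_family


@pytest.fixture(scope="session")
def profiles():
    """(M, K) domain profiles from the bundled seed alignments."""
    return build_profiles()


@pytest.fixture(scope="session")
def small_family():
    """A 10-gene family with 2 type I members, fixed seed."""
    return gen_gene_family(10, 2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_protein(rng, n):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=n))
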