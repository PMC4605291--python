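import numpy as np
import pytest

from idrbind.annotations import AnnotatedProtein
from idrbind.simulate import SimConfig, simulate_corpus

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_protein(rng, length, pid="p"):
    seq = "".join(rng.choice(list(AA), size=length))
    return AnnotatedProtein(id=pid, sequence=seq)


@pytest.fixture
def small_corpus():
    """30-protein corpus with planted signal and homologs (session-stable seed)."""
    cfg = SimConfig(n_proteins=30, length_min=80, length_max=200,
                    homolog_fraction=0.1, seed=11)
    proteins, records, meta = simulate_corpus(cfg)
    return proteins, records, meta
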