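import numpy as np
import pytest

from svsimkit import SVSimConfig, generate_random_svs, make_toy_genome
from svsimkit.events import SVType


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(n_chroms=2, length=30_000, seed=11)


@pytest.fixture(scope="session")
def toy_events(toy_genome):
    cfg = SVSimConfig(counts_by_type={SVType.DEL: 6, SVType.INS: 6, SVType.DUP: 3,
                                      SVType.INV: 3, SVType.CSUB: 3},
                      default_length_range=(50, 400),
                      telomere_window_bp=3000, seed=7)
    return generate_random_svs(cfg, toy_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
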