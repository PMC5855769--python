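import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180211)


@pytest.fixture(scope="session")
def random_dna(rng):
    bases = np.array(list("ACGT"))

    def make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(bases[r.integers(0, 4, n)])

    return make


@pytest.fixture(scope="session")
def small_trio():
    """One modest simulated trio shared across tests that only read it."""
    from igtscan import SimConfig, generate_trio

    cfg = SimConfig(seed=11, species_id="fix01", n_numts=5, n_mtpts=5,
                    nuclear_len=50_000, mt_len=35_000, cp_len=15_000,
                    n_genes=12)
    return generate_trio(cfg)


@pytest.fixture(scope="session")
def sw_aligner():
    from oracles import make_sw_aligner

    return make_sw_aligner()
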