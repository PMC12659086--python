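import numpy as np
import pytest

from plastidflip.genome import build_genome
from plastidflip.population import mutate_population


@pytest.fixture(scope="session")
def small_genome():
    """Toy quadripartite genome: fast for structural tests."""
    return build_genome(8000, 2000, 1500, 2000, n_ir_diffs=2, seed=42)


@pytest.fixture(scope="session")
def mid_genome():
    """Medium genome with 2 kb-flank-capable single-copy regions."""
    return build_genome(20000, 6000, 5000, 6000, n_ir_diffs=3, seed=7)


@pytest.fixture(scope="session")
def full_genome():
    """Default-size genome (135,900 bp)."""
    return build_genome(seed=1)


@pytest.fixture(scope="session")
def mid_population(mid_genome):
    return mutate_population(
        mid_genome,
        6,
        {"LSC": 0.002, "IRa": 0.001, "SSC": 0.002, "IRb": 0.001},
        {"LSC": 0.002, "IRa": 0.002, "SSC": 0.001, "IRb": 0.0005},
        indel_in_repeat_fraction=0.6,
        ir_mirror_prob=1.0,
        sv_spec=[{"region": "LSC", "kind": "ins", "length": 60}],
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
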