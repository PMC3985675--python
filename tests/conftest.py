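import numpy as np
import pytest
from hypothesis import settings

import adaseed as a

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def last_sc():
    return a.last_scheme()


@pytest.fixture(scope="session")
def hoxd70_sc():
    return a.hoxd70_scheme()


@pytest.fixture(scope="session")
def small_pair():
    """A small related genome pair shared across alignment tests."""
    cfg = a.SimulationConfig(
        genome_length=20_000, identity=0.85, ts_tv_ratio=1.5,
        indel_rate=0.01, repeat_fraction=0.05, rng_seed=99,
    )
    return a.synth_genome_pair(cfg)


def random_pattern_text(rng, max_span=10, p=(0.25, 0.35, 0.40)):
    span = int(rng.integers(1, max_span + 1))
    return "".join(rng.choice(list("01T"), size=span, p=list(p)))


def mutate(anc: np.ndarray, rng, sub_rate: float, indel: bool
           ) -> np.ndarray:
    """Derive a mutated copy of a coded sequence (test helper)."""
    der = anc.copy()
    mut = rng.random(anc.size) < sub_rate
    der[mut] = (der[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
    if indel:
        pos = int(rng.integers(20, anc.size - 20))
        ln = int(rng.integers(1, 4))
        der = np.concatenate([der[:pos], der[pos + ln:]])
    return der


def codes_to_text(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)
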