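import logging

import numpy as np
import pytest
from hypothesis import settings

from dedumi.io_reads import Read, ReadSet
from dedumi.simulate import SimulationConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=100)
settings.load_profile("ci")

logging.getLogger("dedumi").setLevel(logging.ERROR)


def make_read(umi: str, seq: str, q: int = 40) -> Read:
    return Read(umi, np.full(len(umi), q, dtype=np.int16), seq, np.full(len(seq), q, dtype=np.int16))


def make_readset(triples, umi_length=None) -> ReadSet:
    """Build a ReadSet from (umi, seq[, qual]) tuples; qual defaults to 40."""
    reads = []
    for t in triples:
        umi, seq = t[0], t[1]
        q = t[2] if len(t) > 2 else 40
        reads.append(make_read(umi, seq, q))
    return ReadSet(reads, umi_length or len(reads[0].umi))


@pytest.fixture(scope="session")
def sim_error_free():
    """Deterministic-doubling, error-free, collision-free simulation where
    every founder molecule is sequenced several times."""
    cfg = SimulationConfig(
        n_reads=6000,
        seed=7,
        cycles=6,
        efficiency=1.0,
        pcr_sub_rates=np.zeros((4, 4)),
        seq_indel_rate=0.0,
        seq_error_scale=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_tiny_noisy():
    """Small noisy simulation for EM behavior tests."""
    cfg = SimulationConfig(
        K=10, n_molecules=100, n_reads=800, cycles=6, seed=11
    )
    return simulate_dataset(cfg)
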