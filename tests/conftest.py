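import numpy as np
import pytest

from memcorrect import dbg
from memcorrect.seqio import SequenceRecord
from memcorrect.simulate import random_genome, simulate_short_reads


@pytest.fixture(scope="session")
def genome_2kb() -> SequenceRecord:
    return random_genome(2000, seed=1)


@pytest.fixture(scope="session")
def genome_20kb() -> SequenceRecord:
    return random_genome(20_000, seed=7)


@pytest.fixture(scope="session")
def perfect_graph_20kb(genome_20kb):
    return dbg.graph_from_sequence(genome_20kb.sequence, k=31)


@pytest.fixture(scope="session")
def tiled_graph_2kb(genome_2kb):
    """Graph from exact 100 bp reads tiling the genome at every position."""
    seq = genome_2kb.sequence
    reads = [
        SequenceRecord(f"t{i}", seq[i : i + 100]) for i in range(0, len(seq) - 99)
    ]
    return dbg.build_graph(reads, k=31)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
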