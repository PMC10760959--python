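import numpy as np
import pytest

from peptigen.synthetic import GenomeConfig, ReadSet, simulate_genome

SMALL_GENOME = GenomeConfig(
    length=20_000,
    n_exons=5,
    orf_codons=(50, 110),
    n_introns=2,
    intron_len=(250, 500),
    n_ere=2,
    ere_len=(250, 500),
    n_hypervariable=1,
    hypervariable_len=(250, 400),
    n_intergenic_tx=1,
)


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(seed=7, config=SMALL_GENOME)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiling_reads(sequence: str, read_len: int = 100, step: int = 1) -> list[str]:
    """Every read of length read_len starting at multiples of step."""
    return [
        sequence[i : i + read_len]
        for i in range(0, len(sequence) - read_len + 1, step)
    ]


def make_readset(reads, sample_id="s1", tissue="tumor") -> ReadSet:
    return ReadSet(sample_id=sample_id, tissue_label=tissue, reads=list(reads))
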