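import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nadda.sequence_io import ProteinSequence, SequenceSet

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_seqs() -> SequenceSet:
    """Two sequences sharing the 2-mers AB, BC, CA."""
    return SequenceSet(
        [ProteinSequence("a", "ABCAB"), ProteinSequence("b", "BCABC")]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_sequence_set(
    rng: np.random.Generator,
    n_max: int = 30,
    len_max: int = 60,
    alphabet: str = "ACDE",
) -> SequenceSet:
    """Small random sequence set over a narrow alphabet (forces k-mer sharing)."""
    n = int(rng.integers(1, n_max + 1))
    letters = list(alphabet)
    seqs = SequenceSet()
    for i in range(n):
        length = int(rng.integers(1, len_max + 1))
        residues = "".join(rng.choice(letters, size=length))
        seqs.add(ProteinSequence(f"s{i}", residues))
    return seqs


def naive_kmer_frequencies(seqs: SequenceSet, k: int) -> dict[str, int]:
    """Independent oracle: per k-mer, count sequences containing it as substring."""
    all_kmers = set()
    for s in seqs:
        for i in range(len(s.residues) - k + 1):
            all_kmers.add(s.residues[i : i + k])
    return {
        kmer: sum(1 for s in seqs if kmer in s.residues) for kmer in all_kmers
    }
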