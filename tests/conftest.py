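import numpy as np
import pytest

from interchange.io import SequenceRecord

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def make_reads(seqs, species="sp"):
    return [SequenceRecord(f"{species}_r{i}", s, species=species)
            for i, s in enumerate(seqs)]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def tile_reads(source: str, read_length: int, step: int, species="sp"):
    """Error-free reads tiling a source sequence end to end."""
    seqs = [source[p:p + read_length]
            for p in range(0, len(source) - read_length + 1, step)]
    if (len(source) - read_length) % step:
        seqs.append(source[-read_length:])
    return make_reads(seqs, species)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
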