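"""Low-complexity read filtering with a whole-read dust score.

Simple and tandem repeats (poly-A runs, (AC)n microsatellites, ...) share
many identical k-mers between unrelated genomes and would flood the
homology screen, so reads dominated by them are removed before assembly.

The score counts repeated overlapping triplets: with c_t the count of
triplet t among the read's N-free overlapping 3-mers,

    dust = 100 * sum_t c_t (c_t - 1) / 2  /  S_max,
    S_max = (W - 2)(W - 3) / 2,  W = effective read length,

so a homopolymer scores exactly 100 and a read whose triplets are all
distinct scores exactly 0. Triplets containing N are excluded and W reduced
accordingly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io import SequenceRecord

__all__ = ["ComplexityScore", "dust_score", "filter_low_complexity"]


@dataclass(frozen=True)
class ComplexityScore:
    read_id: str
    dust: float


def dust_score(sequence: str) -> float:
    """Whole-read dust score in [0, 100]."""
    seq = sequence.upper()
    if len(seq) < 4:
        raise ValueError("dust score undefined for sequences shorter than 4 bp")
    counts: Counter[str] = Counter()
    n_trip = 0
    for i in range(len(seq) - 2):
        t = seq[i:i + 3]
        if "N" in t:
            continue
        counts[t] += 1
        n_trip += 1
    # effective length: W - 2 valid triplets
    w = n_trip + 2
    if w < 4:
        raise ValueError("dust score undefined: fewer than 2 N-free triplets")
    s = sum(c * (c - 1) // 2 for c in counts.values())
    s_max = (w - 2) * (w - 3) / 2
    return 100.0 * s / s_max


def filter_low_complexity(
    reads: Sequence[SequenceRecord], threshold: float = 10.0
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition reads into (retained, rejected) at the dust threshold.

    A read is rejected iff dust > threshold, i.e. a read exactly at the
    threshold is kept. The partition is exhaustive and disjoint.
    """
    if not (0 <= threshold <= 100):
        raise ValueError("threshold must be in [0, 100]")
    retained, rejected = [], []
    for rec in reads:
        (rejected if dust_score(rec.sequence) > threshold else retained).append(rec)
    return retained, rejected
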