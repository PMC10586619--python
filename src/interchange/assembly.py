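"""Minimal de Bruijn assembly of the retained homologous reads.

Each species' retained reads are assembled separately; the resulting
scaffolds represent the conserved loci the read screen detected. The
assembler is deliberately small: canonical k-mer graph, dead-end tips
shorter than 2k and low-depth bubble branches removed, maximal unbranched
paths emitted. It is built for short, high-identity, error-light read sets
(the screen's output), not for whole genomes; an external assembler can be
substituted through the ``assembler`` hook of the pipeline for real data.

Determinism: traversal order is lexicographic in the canonical k-mer
strings, so identical input yields identical scaffolds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io import SequenceRecord

__all__ = ["Scaffold", "assemble"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class Scaffold:
    id: str
    species: str
    sequence: str
    supporting_read_count: int
    mean_depth: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def _kmer_counts(reads: Sequence[SequenceRecord], k: int) -> Counter:
    counts: Counter[str] = Counter()
    for rec in reads:
        s = rec.sequence
        if len(s) < k:
            continue
        r = revcomp(s)
        L = len(s)
        for i in range(L - k + 1):
            f = s[i:i + k]
            if "N" in f:
                continue
            rcw = r[L - k - i:L - i]
            counts[f if f <= rcw else rcw] += 1
    return counts


class _Graph:
    def __init__(self, counts: Counter, k: int):
        self.counts = counts
        self.k = k

    def successors(self, kmer: str) -> list[str]:
        suf = kmer[1:]
        return [suf + b for b in "ACGT" if _canon(suf + b) in self.counts]

    def predecessors(self, kmer: str) -> list[str]:
        pre = kmer[:-1]
        return [b + pre for b in "ACGT" if _canon(b + pre) in self.counts]


@dataclass
class _Unitig:
    kmers: list[str]  # oriented k-mers along the path

    def sequence(self, k: int) -> str:
        return self.kmers[0] + "".join(km[-1] for km in self.kmers[1:])


def _build_unitigs(graph: _Graph) -> list[_Unitig]:
    visited: set[str] = set()
    unitigs: list[_Unitig] = []

    def _walk(start: str) -> list[str]:
        path = []
        cur = start
        while True:
            succs = graph.successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if _canon(nxt) in visited:
                break
            if len(graph.predecessors(nxt)) != 1:
                break
            visited.add(_canon(nxt))
            path.append(nxt)
            cur = nxt
        return path

    for key in sorted(graph.counts):
        if key in visited:
            continue
        visited.add(key)
        right = _walk(key)
        left = _walk(revcomp(key))
        path = [revcomp(km) for km in reversed(left)] + [key] + right
        unitigs.append(_Unitig(path))
    return unitigs


def _remove_tips_and_bubbles(counts: Counter, k: int, max_rounds: int = 5) -> None:
    """Iteratively drop dangling tips < 2k and bubble branches < 10% sibling depth."""
    for _ in range(max_rounds):
        graph = _Graph(counts, k)
        unitigs = _build_unitigs(graph)
        doomed: set[str] = set()
        # endpoint junction sets per unitig
        ends = []
        for u in unitigs:
            preds = frozenset(_canon(p) for p in graph.predecessors(u.kmers[0]))
            succs = frozenset(_canon(s) for s in graph.successors(u.kmers[-1]))
            depth = sum(counts[_canon(km)] for km in u.kmers) / len(u.kmers)
            ends.append((preds, succs, depth))
        # tips: one free end, short
        for u, (preds, succs, _d) in zip(unitigs, ends):
            seqlen = len(u.kmers) + k - 1
            if seqlen < 2 * k and (len(preds) == 0) != (len(succs) == 0):
                doomed.update(_canon(km) for km in u.kmers)
        # bubbles: same junctions on both sides, much lower depth than sibling
        groups: dict[tuple, list[int]] = {}
        for i, (preds, succs, _d) in enumerate(ends):
            if preds and succs:
                fwd = (preds, succs)
                rev = (succs, preds)
                key = min(fwd, rev, key=lambda t: (sorted(t[0]), sorted(t[1])))
                groups.setdefault(key, []).append(i)
        for members in groups.values():
            if len(members) < 2:
                continue
            best = max(ends[i][2] for i in members)
            for i in members:
                if ends[i][2] < 0.10 * best:
                    doomed.update(_canon(km) for km in unitigs[i].kmers)
        if not doomed:
            return
        for km in doomed:
            counts.pop(km, None)


def assemble(
    reads: Sequence[SequenceRecord],
    k_asm: int = 55,
    species: str = "",
    min_kmer_count: int = 1,
) -> list[Scaffold]:
    """Assemble reads into scaffolds; output sorted by length descending.

    Scaffold ids are ``{species}_{ordinal}`` with ordinals assigned after
    sorting. Scaffold sequences are emitted in canonical orientation
    (lexicographic minimum of the two strands) for determinism.
    """
    if k_asm % 2 == 0 or not (21 <= k_asm):
        raise ValueError("k_asm must be odd and >= 21")
    if not reads:
        return []
    if k_asm >= max(len(r.sequence) for r in reads):
        raise ValueError("k_asm must be smaller than the read length")
    counts = _kmer_counts(reads, k_asm)
    if min_kmer_count > 1:
        counts = Counter({km: c for km, c in counts.items() if c >= min_kmer_count})
    _remove_tips_and_bubbles(counts, k_asm)
    graph = _Graph(counts, k_asm)
    unitigs = _build_unitigs(graph)

    seqs = []
    for u in unitigs:
        seq = u.sequence(k_asm)
        if len(seq) < k_asm:
            continue
        depth = sum(counts[_canon(km)] for km in u.kmers) / len(u.kmers)
        canon_seq = min(seq, revcomp(seq))
        seqs.append((canon_seq, depth, u))
    seqs.sort(key=lambda t: (-len(t[0]), t[0]))

    # read support: a read supports a scaffold when any of its k-mers lies on it
    owner: dict[str, int] = {}
    for idx, (_seq, _depth, u) in enumerate(seqs):
        for km in u.kmers:
            owner[_canon(km)] = idx
    support = [0] * len(seqs)
    for rec in reads:
        s = rec.sequence
        hit: set[int] = set()
        for i in range(len(s) - k_asm + 1):
            w = s[i:i + k_asm]
            if "N" in w:
                continue
            j = owner.get(_canon(w))
            if j is not None:
                hit.add(j)
        for j in hit:
            support[j] += 1

    prefix = species if species else "scaffold"
    return [
        Scaffold(
            id=f"{prefix}_{i + 1}",
            species=species,
            sequence=seq,
            supporting_read_count=max(1, support[i]),
            mean_depth=depth,
        )
        for i, (seq, depth, _u) in enumerate(seqs)
    ]
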