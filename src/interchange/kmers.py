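"""Cross-species read homology screen based on shared identical k-mers.

Every k-window of every read (windows containing N are skipped) is encoded
as a 2-bit-packed integer and stored under its canonical form, the
lexicographic minimum of the forward window and its reverse complement, so
reverse-strand homology is found. Reads of two species sharing canonical
k-mers are paired; per read of a pair the positions covered by shared
k-mers are merged (interval union) and the read similarity is the merged
span divided by the read length. A pair whose smaller per-read similarity
reaches the threshold (default 50%) is called homologous.

The whole screen is vectorized: k-mers live in sorted uint64 arrays and
pair scoring uses grouped reductions, so tens of millions of windows are
practical on one core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "KmerIndex",
    "ReadPairScore",
    "build_kmer_index",
    "find_shared_hits",
    "score_read_pair",
    "score_all_pairs",
    "retain_homologous_pairs",
    "encode_sequence",
    "canonical_kmers",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

MAX_K = 31  # 2 bits per base in a uint64


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes (A=0,C=1,G=2,T=3); anything else (incl. N) becomes 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int):
    """Canonical k-mer codes of all valid windows of one sequence.

    Returns ``(kmers, offsets, strands)`` where ``strands`` is True when the
    forward orientation is the canonical one. Windows containing N are
    absent.
    """
    codes = encode_sequence(seq)[None, :]
    km, off, strand, _ = _windows_batch(codes, k)
    return km, off, strand


def _windows_batch(codes: np.ndarray, k: int):
    """Canonical windows for a (n_reads, L) code matrix.

    Returns flat arrays (kmer, offset, fwd_is_canonical, row) over all valid
    windows of all rows.
    """
    n, L = codes.shape
    if L < k:
        e = np.empty(0, dtype=np.uint64)
        return e, e.astype(np.int32), e.astype(bool), e.astype(np.int64)
    nw = L - k + 1
    mask = np.uint64((1 << (2 * k)) - 1)
    shift_hi = np.uint64(2 * (k - 1))
    valid_base = codes < 4
    c = np.where(valid_base, codes, 0).astype(np.uint64)
    rc = np.uint64(3) - c
    fwd = np.zeros((n, nw), dtype=np.uint64)
    rev = np.zeros((n, nw), dtype=np.uint64)
    f = np.zeros(n, dtype=np.uint64)
    r = np.zeros(n, dtype=np.uint64)
    for j in range(L):
        f = ((f << np.uint64(2)) | c[:, j]) & mask
        r = (r >> np.uint64(2)) | (rc[:, j] << shift_hi)
        if j >= k - 1:
            fwd[:, j - k + 1] = f
            rev[:, j - k + 1] = r
    # window valid iff its k bases are all ACGT
    cs = np.zeros((n, L + 1), dtype=np.int32)
    np.cumsum(~valid_base, axis=1, out=cs[:, 1:])
    ok = (cs[:, k:] - cs[:, :-k]) == 0
    strand = fwd <= rev
    canon = np.where(strand, fwd, rev)
    rows, offs = np.nonzero(ok)
    return canon[rows, offs], offs.astype(np.int32), strand[rows, offs], rows


def _batched_codes(reads: Sequence[SequenceRecord]) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Group reads by length into code matrices, yielding (codes, read_ids)."""
    by_len: dict[int, list[int]] = {}
    for i, rec in enumerate(reads):
        by_len.setdefault(len(rec.sequence), []).append(i)
    for L, idxs in sorted(by_len.items()):
        mat = np.empty((len(idxs), L), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = encode_sequence(reads[i].sequence)
        yield mat, np.asarray(idxs, dtype=np.int64)


class _Windows(NamedTuple):
    kmers: np.ndarray  # uint64 canonical codes
    reads: np.ndarray  # read ordinals
    offsets: np.ndarray
    strands: np.ndarray  # True = forward orientation is canonical


def _all_windows(reads: Sequence[SequenceRecord], k: int) -> _Windows:
    parts = []
    for codes, ids in _batched_codes(reads):
        km, off, strand, rows = _windows_batch(codes, k)
        parts.append((km, ids[rows], off, strand))
    if not parts:
        e = np.empty(0, dtype=np.uint64)
        return _Windows(e, e.astype(np.int64), e.astype(np.int32), e.astype(bool))
    return _Windows(*(np.concatenate(cols) for cols in zip(*parts)))


@dataclass
class KmerIndex:
    """Sorted canonical k-mer index over one species' reads."""

    k: int
    kmers: np.ndarray  # sorted uint64
    reads: np.ndarray
    offsets: np.ndarray
    strands: np.ndarray
    min_occurrence: int = 1
    read_lengths: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.kmers)

    def entries(self) -> dict[int, list[tuple[int, int, bool]]]:
        """Mapping canonical k-mer -> [(read ordinal, offset, fwd strand)].

        Materialized view for inspection and small-scale testing; the arrays
        are the working representation.
        """
        out: dict[int, list[tuple[int, int, bool]]] = {}
        for km, rd, off, st in zip(
            self.kmers.tolist(), self.reads.tolist(),
            self.offsets.tolist(), self.strands.tolist(),
        ):
            out.setdefault(km, []).append((rd, off, st))
        return out


def build_kmer_index(
    reads: Sequence[SequenceRecord], k: int, min_occurrence: int = 1
) -> KmerIndex:
    """Index every N-free k-window of every read under its canonical form.

    k-mers seen fewer than ``min_occurrence`` times in the whole read set
    are dropped (the published protocol uses minimum occurrence 1, i.e. no
    dropping).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    win = _all_windows(reads, k)
    order = np.argsort(win.kmers, kind="stable")
    km = win.kmers[order]
    rd = win.reads[order]
    off = win.offsets[order]
    st = win.strands[order]
    if min_occurrence > 1 and len(km):
        uniq, counts = np.unique(km, return_counts=True)
        keep_vals = uniq[counts >= min_occurrence]
        keep = np.isin(km, keep_vals)
        km, rd, off, st = km[keep], rd[keep], off[keep], st[keep]
    lengths = np.asarray([len(r.sequence) for r in reads], dtype=np.int32)
    return KmerIndex(k, km, rd, off, st, min_occurrence, lengths)


class KmerHits(NamedTuple):
    """Shared-k-mer occurrences between indexed reads (a) and query reads (b).

    ``strand`` is True when the two occurrences have the same orientation.
    Intervals on each read are ``[offset, offset + k)``.
    """

    k: int
    read_a: np.ndarray
    read_b: np.ndarray
    offset_a: np.ndarray
    offset_b: np.ndarray
    strand: np.ndarray

    def __len__(self) -> int:
        return len(self.read_a)

    def tuples(self):
        k = self.k
        for ra, rb, oa, ob, st in zip(
            self.read_a.tolist(), self.read_b.tolist(),
            self.offset_a.tolist(), self.offset_b.tolist(), self.strand.tolist(),
        ):
            yield ra, rb, (oa, oa + k), (ob, ob + k), ("+" if st else "-")


def find_shared_hits(
    index_a: KmerIndex,
    reads_b: Sequence[SequenceRecord],
    chunk_size: int = 2_000_000,
) -> KmerHits:
    """All occurrences of canonical k-mers of ``reads_b`` present in ``index_a``.

    One hit per occurrence pair; an empty result when nothing is shared.
    """
    k = index_a.k
    win_b = _all_windows(reads_b, k)
    parts = []
    for lo in range(0, len(win_b.kmers), chunk_size):
        sl = slice(lo, lo + chunk_size)
        kb = win_b.kmers[sl]
        left = np.searchsorted(index_a.kmers, kb, side="left")
        right = np.searchsorted(index_a.kmers, kb, side="right")
        counts = right - left
        hit_b = np.nonzero(counts)[0]
        if not len(hit_b):
            continue
        counts_h = counts[hit_b]
        # expand: for each b window, the run of matching index rows
        idx_a = np.repeat(left[hit_b], counts_h) + _run_aranges(counts_h)
        idx_b = np.repeat(hit_b, counts_h)
        parts.append(
            (
                index_a.reads[idx_a],
                win_b.reads[sl][idx_b],
                index_a.offsets[idx_a],
                win_b.offsets[sl][idx_b],
                index_a.strands[idx_a] == win_b.strands[sl][idx_b],
            )
        )
    if not parts:
        e = np.empty(0, dtype=np.int64)
        return KmerHits(k, e, e, e.astype(np.int32), e.astype(np.int32), e.astype(bool))
    cols = [np.concatenate(c) for c in zip(*parts)]
    return KmerHits(k, *cols)


def _run_aranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated [0..c) ranges for a vector of run lengths."""
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = -(counts[:-1] - 1)
    return np.cumsum(out)


@dataclass(frozen=True)
class ReadPairScore:
    """Merged shared-k-mer spans and similarities for one cross-species pair."""

    read_a: int
    read_b: int
    merged_span_a: int
    merged_span_b: int
    similarity_a: float
    similarity_b: float

    @property
    def pair_similarity(self) -> float:
        return min(self.similarity_a, self.similarity_b)


def _merged_span(offsets: Iterable[int], k: int) -> int:
    """Length of the union of [o, o+k) intervals."""
    offs = sorted(set(offsets))
    if not offs:
        return 0
    span = k
    for prev, cur in zip(offs, offs[1:]):
        span += min(k, cur - prev)
    return span


def score_read_pair(hits: KmerHits, read_a: int, read_b: int,
                    length_a: int, length_b: int) -> ReadPairScore:
    """Score one read pair from its shared-k-mer hits.

    Overlapping k-mer intervals on each read are merged before summing, so
    the span is the number of distinct covered positions.
    """
    sel = (hits.read_a == read_a) & (hits.read_b == read_b)
    span_a = _merged_span(hits.offset_a[sel].tolist(), hits.k)
    span_b = _merged_span(hits.offset_b[sel].tolist(), hits.k)
    return ReadPairScore(
        read_a, read_b, span_a, span_b,
        span_a / length_a, span_b / length_b,
    )


class PairScores(NamedTuple):
    """Vectorized per-pair scores over all hit read pairs."""

    read_a: np.ndarray
    read_b: np.ndarray
    span_a: np.ndarray
    span_b: np.ndarray
    similarity_a: np.ndarray
    similarity_b: np.ndarray

    @property
    def pair_similarity(self) -> np.ndarray:
        return np.minimum(self.similarity_a, self.similarity_b)

    def __len__(self) -> int:
        return len(self.read_a)

    def records(self) -> list[ReadPairScore]:
        return [
            ReadPairScore(int(ra), int(rb), int(sa), int(sb), float(fa), float(fb))
            for ra, rb, sa, sb, fa, fb in zip(
                self.read_a, self.read_b, self.span_a, self.span_b,
                self.similarity_a, self.similarity_b,
            )
        ]


def _grouped_union_span(key: np.ndarray, offsets: np.ndarray, k: int):
    """Union-of-intervals span per group key; returns (unique keys, spans)."""
    order = np.lexsort((offsets, key))
    ks = key[order]
    os = offsets[order].astype(np.int64)
    new = np.ones(len(ks), dtype=bool)
    new[1:] = ks[1:] != ks[:-1]
    diff = np.empty(len(os), dtype=np.int64)
    diff[0] = k
    diff[1:] = np.minimum(os[1:] - os[:-1], k)
    diff[new] = k
    starts = np.nonzero(new)[0]
    spans = np.add.reduceat(diff, starts)
    return ks[starts], spans


def score_all_pairs(
    hits: KmerHits,
    lengths_a: np.ndarray,
    lengths_b: np.ndarray,
) -> PairScores:
    """Merged spans and similarities for every read pair appearing in hits."""
    if len(hits) == 0:
        e = np.empty(0, dtype=np.int64)
        f = np.empty(0, dtype=np.float64)
        return PairScores(e, e, e, e, f, f)
    key = hits.read_a.astype(np.uint64) << np.uint64(32)
    key |= hits.read_b.astype(np.uint64)
    keys_a, span_a = _grouped_union_span(key, hits.offset_a, hits.k)
    keys_b, span_b = _grouped_union_span(key, hits.offset_b, hits.k)
    assert np.array_equal(keys_a, keys_b)
    ra = (keys_a >> np.uint64(32)).astype(np.int64)
    rb = (keys_a & np.uint64(0xFFFFFFFF)).astype(np.int64)
    la = np.asarray(lengths_a)[ra]
    lb = np.asarray(lengths_b)[rb]
    return PairScores(ra, rb, span_a, span_b, span_a / la, span_b / lb)


def read_similarities(
    reads: Sequence[SequenceRecord], other_index: KmerIndex
) -> np.ndarray:
    """Per-read similarity against the other species' whole k-mer index.

    A read's merged span is the union of its k-windows whose canonical form
    occurs anywhere in the other index — the read-versus-index analogue of
    per-pair scoring, matching a k-mer search that reports query positions
    without subject identities. Returns S = span / length per read.
    """
    k = other_index.k
    win = _all_windows(reads, k)
    uniq = np.unique(other_index.kmers)
    if len(uniq):
        pos = np.minimum(np.searchsorted(uniq, win.kmers), len(uniq) - 1)
        hit = uniq[pos] == win.kmers
    else:
        hit = np.zeros(len(win.kmers), dtype=bool)
    spans = np.zeros(len(reads), dtype=np.int64)
    if hit.any():
        rid, sp = _grouped_union_span(
            win.reads[hit].astype(np.uint64), win.offsets[hit], k
        )
        spans[rid.astype(np.int64)] = sp
    lengths = np.asarray([len(r.sequence) for r in reads], dtype=np.int64)
    return spans / lengths


def retain_homologous_reads(
    reads_a: Sequence[SequenceRecord],
    reads_b: Sequence[SequenceRecord],
    k: int,
    threshold: float,
    min_occurrence: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric per-read retention: keep reads with S >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    index_a = build_kmer_index(reads_a, k, min_occurrence)
    index_b = build_kmer_index(reads_b, k, min_occurrence)
    sim_a = read_similarities(reads_a, index_b)
    sim_b = read_similarities(reads_b, index_a)
    return np.nonzero(sim_a >= threshold)[0], np.nonzero(sim_b >= threshold)[0]


def retain_homologous_pairs(
    scores: PairScores | Sequence[ReadPairScore], threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Read ordinals retained per species at the pair-similarity threshold.

    A pair is retained iff min(S_a, S_b) >= threshold (boundary inclusive);
    each retained read appears once however many partners it has.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if not isinstance(scores, PairScores):
        ra = np.asarray([s.read_a for s in scores], dtype=np.int64)
        rb = np.asarray([s.read_b for s in scores], dtype=np.int64)
        sim = np.asarray([s.pair_similarity for s in scores])
    else:
        ra, rb, sim = scores.read_a, scores.read_b, scores.pair_similarity
    keep = sim >= threshold
    return np.unique(ra[keep]), np.unique(rb[keep])
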