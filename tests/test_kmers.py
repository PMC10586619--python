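"""Shared-k-mer screen against brute-force string-comparison oracles."""

import numpy as np
import pytest

from interchange import kmers
from interchange.io import SequenceRecord

from conftest import make_reads, random_dna, revcomp


def brute_shared_positions(seq_a: str, seq_b: str, k: int):
    """Positions of seq_a covered by any k-substring present in seq_b
    (either strand) — direct string comparison, no indexing."""
    subs = set()
    for j in range(len(seq_b) - k + 1):
        w = seq_b[j:j + k]
        if "N" not in w:
            subs.add(w)
            subs.add(revcomp(w))
    covered = set()
    for i in range(len(seq_a) - k + 1):
        w = seq_a[i:i + k]
        if "N" not in w and w in subs:
            covered.update(range(i, i + k))
    return covered


def test_window_count_is_length_minus_k_plus_one():
    idx = kmers.build_kmer_index(make_reads(["ACGTACGT"]), 8)
    assert len(idx) == 1
    idx = kmers.build_kmer_index(make_reads(["ACGTACGTACGT"]), 8)
    assert len(idx) == 5


def test_small_k_rejected():
    with pytest.raises(ValueError):
        kmers.build_kmer_index(make_reads(["ACGTACGTACGT"]), 4)


def test_windows_overlapping_n_are_absent(rng):
    seq = random_dna(rng, 61)
    seq = seq[:30] + "N" + seq[31:]
    idx = kmers.build_kmer_index(make_reads([seq]), 30)
    # valid windows: those entirely inside [0,30) start range minus N overlap
    offs = sorted(idx.offsets.tolist())
    assert offs == [0, 31]


def test_canonicalization_matches_brute_force(rng):
    seq = random_dna(rng, 60)
    k = 12
    km, off, strand = kmers.canonical_kmers(seq, k)
    # brute force canonical strings
    def enc(s):
        v = 0
        for c in s:
            v = (v << 2) | "ACGT".index(c)
        return v
    expect = []
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        expect.append(min(enc(w), enc(revcomp(w))))
    assert km.tolist() == expect
    # forward-strand flag set iff the forward word is the canonical one
    for i, s in zip(off.tolist(), strand.tolist()):
        w = seq[i:i + k]
        assert s == (enc(w) <= enc(revcomp(w)))


def test_min_occurrence_drops_singletons(rng):
    seq = random_dna(rng, 40)
    reads = make_reads([seq, seq, random_dna(rng, 40)])
    idx = kmers.build_kmer_index(reads, 20, min_occurrence=2)
    # only the duplicated read's k-mers survive
    assert set(idx.reads.tolist()) == {0, 1}


def test_identical_read_produces_all_window_hits(rng):
    seq = random_dna(rng, 150)
    idx = kmers.build_kmer_index(make_reads([seq], "a"), 30)
    hits = kmers.find_shared_hits(idx, make_reads([seq], "b"))
    assert len(hits) == 150 - 30 + 1
    assert bool(hits.strand.all())


def test_reverse_complement_read_hits_on_opposite_strand(rng):
    seq = random_dna(rng, 150)
    idx = kmers.build_kmer_index(make_reads([seq], "a"), 30)
    hits = kmers.find_shared_hits(idx, make_reads([revcomp(seq)], "b"))
    assert len(hits) == 121
    assert not hits.strand.any()


def test_disjoint_random_reads_share_nothing(rng):
    reads_a = make_reads([random_dna(rng, 150) for _ in range(20)], "a")
    reads_b = make_reads([random_dna(rng, 150) for _ in range(20)], "b")
    idx = kmers.build_kmer_index(reads_a, 30)
    assert len(kmers.find_shared_hits(idx, reads_b)) == 0


def test_score_identical_reads_reaches_one(rng):
    seq = random_dna(rng, 150)
    idx = kmers.build_kmer_index(make_reads([seq], "a"), 30)
    hits = kmers.find_shared_hits(idx, make_reads([seq], "b"))
    score = kmers.score_read_pair(hits, 0, 0, 150, 150)
    assert score.merged_span_a == 150
    assert score.similarity_a == 1.0
    assert score.pair_similarity == 1.0


def test_single_shared_kmer_scores_k_over_length(rng):
    a = random_dna(rng, 150)
    b = random_dna(rng, 150)
    shared = random_dna(rng, 30)

    def flip(c):  # a base different from c, so the match cannot extend
        return {"A": "C", "C": "G", "G": "T", "T": "A"}[c]

    b = b[:100] + shared + b[130:]
    # place the block at a[40:70] with flanks mismatching b's flanks
    a = a[:39] + flip(b[99]) + shared + flip(b[130]) + a[71:]
    assert len(a) == 150
    idx = kmers.build_kmer_index(make_reads([a], "a"), 30)
    hits = kmers.find_shared_hits(idx, make_reads([b], "b"))
    score = kmers.score_read_pair(hits, 0, 0, 150, 150)
    assert score.merged_span_a == len(brute_shared_positions(a, b, 30))
    assert score.merged_span_a == 30
    assert score.similarity_a == pytest.approx(0.2)


def test_overlapping_kmers_merge_to_union():
    # shared k-mers at offsets 0 and 10 with k=30 cover [0, 40)
    hits = kmers.KmerHits(
        k=30,
        read_a=np.array([0, 0]), read_b=np.array([0, 0]),
        offset_a=np.array([0, 10]), offset_b=np.array([0, 10]),
        strand=np.array([True, True]),
    )
    score = kmers.score_read_pair(hits, 0, 0, 150, 150)
    assert score.merged_span_a == 40
    assert score.similarity_a == pytest.approx(40 / 150)


def test_empty_hits_score_zero():
    hits = kmers.KmerHits(
        30, np.empty(0, int), np.empty(0, int),
        np.empty(0, int), np.empty(0, int), np.empty(0, bool),
    )
    score = kmers.score_read_pair(hits, 0, 1, 150, 150)
    assert score.merged_span_a == 0 and score.pair_similarity == 0.0


def test_retention_boundary_inclusive_and_min_rule():
    mk = lambda ra, rb, sa, sb: kmers.ReadPairScore(ra, rb, int(sa * 150), int(sb * 150), sa, sb)
    scores = [mk(0, 0, 0.5, 0.5), mk(1, 1, 0.9, 0.4)]
    ids_a, ids_b = kmers.retain_homologous_pairs(scores, 0.5)
    assert ids_a.tolist() == [0] and ids_b.tolist() == [0]


def test_merged_spans_match_brute_force_on_random_pairs(rng):
    """Vectorized spans equal direct string comparison on reads <= 200 bp."""
    k = 11
    for _ in range(30):
        la, lb = rng.integers(k, 201, 2)
        a, b = random_dna(rng, la), random_dna(rng, lb)
        if rng.random() < 0.7:  # plant a shared block
            blk = random_dna(rng, int(rng.integers(k, 40)))
            blk = blk[: min(len(blk), la, lb)]
            ai = int(rng.integers(0, la - len(blk) + 1))
            bi = int(rng.integers(0, lb - len(blk) + 1))
            a = a[:ai] + blk + a[ai + len(blk):]
            ins = blk if rng.random() < 0.5 else revcomp(blk)
            b = b[:bi] + ins + b[bi + len(blk):]
        idx = kmers.build_kmer_index(make_reads([a], "a"), k)
        hits = kmers.find_shared_hits(idx, make_reads([b], "b"))
        if len(hits) == 0:
            assert not brute_shared_positions(a, b, k)
            continue
        scores = kmers.score_all_pairs(hits, np.array([la]), np.array([lb]))
        assert scores.span_a[0] == len(brute_shared_positions(a, b, k))
        assert scores.span_b[0] == len(brute_shared_positions(b, a, k))


def test_retained_set_is_symmetric_between_species(rng):
    reads_a = make_reads([random_dna(rng, 100) for _ in range(30)], "a")
    shared = [r.sequence for r in reads_a[:10]]
    reads_b = make_reads(shared + [random_dna(rng, 100) for _ in range(20)], "b")
    ids_a, ids_b = kmers.retain_homologous_reads(reads_a, reads_b, 21, 0.5)
    ids_b2, ids_a2 = kmers.retain_homologous_reads(reads_b, reads_a, 21, 0.5)
    assert ids_a.tolist() == ids_a2.tolist()
    assert ids_b.tolist() == ids_b2.tolist()
    assert set(ids_a.tolist()) == set(range(10))


def test_raising_threshold_never_adds_pairs(rng):
    reads_a = make_reads([random_dna(rng, 120) for _ in range(20)], "a")
    mix = [r.sequence[:60] + random_dna(rng, 60) for r in reads_a[:10]]
    reads_b = make_reads(mix, "b")
    idx = kmers.build_kmer_index(reads_a, 21)
    hits = kmers.find_shared_hits(idx, reads_b)
    scores = kmers.score_all_pairs(
        hits, np.full(20, 120), np.full(10, 120)
    )
    prev = None
    for thr in (0.2, 0.4, 0.6, 0.8):
        ids_a, _ = kmers.retain_homologous_pairs(scores, thr)
        cur = set(ids_a.tolist())
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_per_read_similarity_matches_brute_force(rng):
    reads_a = make_reads([random_dna(rng, 100) for _ in range(10)], "a")
    reads_b = make_reads(
        [r.sequence[:50] + random_dna(rng, 50) for r in reads_a], "b"
    )
    idx_b = kmers.build_kmer_index(reads_b, 21)
    sims = kmers.read_similarities(reads_a, idx_b)
    for ra, s in zip(reads_a, sims):
        covered = set()
        for rb in reads_b:
            covered |= brute_shared_positions(ra.sequence, rb.sequence, 21)
        assert s == pytest.approx(len(covered) / 100)
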