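"""Seed-and-extend alignment used for annotation, RBH pairing and screening.

Nucleotide mode seeds with exact 11-mers, clusters seeds by diagonal and
extends each cluster with a banded edit-distance alignment (edlib), then
rescores the resulting alignment path with the declared scheme
(match +1, mismatch -2, gap open -5, gap extend -2; a length-L gap costs
5 + 2(L-1)). Translated mode translates the query in six frames (internal
stops kept, since transposon ORFs are often fragmented), seeds with exact
amino-acid 4-mers and extends with a BLOSUM62 local alignment
(gap open -11, extend -1) via Biopython's PairwiseAligner.

No e-values are computed: built-in filtering uses identity and coverage
floors (0.70 nucleotide / 0.30 translated identity, 0.30 query coverage),
exposed in the run configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .assembly import revcomp
from .io import SequenceRecord

__all__ = [
    "AlignmentHit",
    "LocalHit",
    "local_hits",
    "best_local_alignment",
    "seed_extend_align",
    "global_identity",
    "six_frame_translate",
    "map_reads_depth",
]

NUC_SEED_K = 11
AA_SEED_K = 4
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
MIN_IDENTITY_NUC = 0.70
MIN_IDENTITY_AA = 0.30
MIN_COVERAGE = 0.30

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class LocalHit:
    """One extended local alignment between a query and a target sequence.

    Coordinates are 0-based half-open on the forward strands; ``strand`` is
    '-' when the reverse complement of the query aligned.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    aln_len: int
    identity: float
    score: int


@dataclass(frozen=True)
class AlignmentHit:
    """Best alignment of one query against one database entry."""

    query_id: str
    subject_id: str
    db_tag: str
    identity: float
    alignment_length: int
    query_coverage: float
    score: float
    mode: str
    superfamily: Optional[str] = None
    lineage: Optional[str] = None


def _parse_cigar(cigar: str) -> tuple[int, int, int]:
    """(matches, alignment_length, score) from an extended CIGAR."""
    matches = aln_len = score = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        aln_len += n
        if op == "=":
            matches += n
            score += MATCH * n
        elif op in "XM":
            score += MISMATCH * n
        else:  # I or D
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return matches, aln_len, score


def _seed_positions(target: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        w = target[i:i + k]
        if "N" in w:
            continue
        idx.setdefault(w, []).append(i)
    return idx


def _cluster_seeds(seeds: list[tuple[int, int]], band: int, max_gap: int):
    """Group (qpos, tpos) seeds by diagonal proximity and query continuity."""
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    for q, t in seeds:
        d = t - q
        placed = False
        for cl in clusters:
            q0, t0 = cl[-1]
            if abs(d - (t0 - q0)) <= band and abs(q - q0) <= max_gap:
                cl.append((q, t))
                placed = True
                break
        if placed:
            continue
        clusters.append([(q, t)])
    return clusters


def _extend_cluster(
    query: str, target: str, cluster, seed_k: int, pad: int = 25
) -> Optional[LocalHit]:
    qs = min(q for q, _ in cluster)
    qe = max(q for q, _ in cluster) + seed_k
    ts = min(t for _, t in cluster)
    te = max(t for _, t in cluster) + seed_k
    q_lo = max(0, qs - pad)
    q_hi = min(len(query), qe + pad)
    t_lo = max(0, ts - pad - seed_k)
    t_hi = min(len(target), te + pad + seed_k)
    res = edlib.align(query[q_lo:q_hi], target[t_lo:t_hi], mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches, aln_len, score = _parse_cigar(res["cigar"])
    loc = res["locations"][0]
    return LocalHit(
        q_start=q_lo,
        q_end=q_hi,
        t_start=t_lo + loc[0],
        t_end=t_lo + loc[1] + 1,
        strand="+",
        matches=matches,
        aln_len=aln_len,
        identity=matches / aln_len if aln_len else 0.0,
        score=score,
    )


def local_hits(
    query: str,
    target: str,
    seed_k: int = NUC_SEED_K,
    band: int = 30,
    max_gap: int = 400,
    both_strands: bool = True,
) -> list[LocalHit]:
    """Seeded local alignments of query against target, best first."""
    if len(query) < seed_k or len(target) < seed_k:
        return []
    idx = _seed_positions(target, seed_k)
    out: list[LocalHit] = []
    variants = [("+", query)]
    if both_strands:
        variants.append(("-", revcomp(query)))
    for strand, qseq in variants:
        seeds = []
        for i in range(len(qseq) - seed_k + 1):
            for t in idx.get(qseq[i:i + seed_k], ()):
                seeds.append((i, t))
        if not seeds:
            continue
        for cl in _cluster_seeds(seeds, band, max_gap):
            hit = _extend_cluster(qseq, target, cl, seed_k)
            if hit is None:
                continue
            if strand == "-":
                hit = LocalHit(
                    q_start=len(query) - hit.q_end,
                    q_end=len(query) - hit.q_start,
                    t_start=hit.t_start,
                    t_end=hit.t_end,
                    strand="-",
                    matches=hit.matches,
                    aln_len=hit.aln_len,
                    identity=hit.identity,
                    score=hit.score,
                )
            out.append(hit)
    out.sort(key=lambda h: (-h.score, h.q_start, h.t_start))
    return _drop_query_duplicates(out)


def _drop_query_duplicates(hits: list[LocalHit], max_overlap: float = 0.5):
    """Keep the best hit per roughly-duplicated query interval."""
    kept: list[LocalHit] = []
    for h in hits:
        dup = False
        for g in kept:
            ov = min(h.q_end, g.q_end) - max(h.q_start, g.q_start)
            if ov > max_overlap * (h.q_end - h.q_start):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def best_local_alignment(query: str, target: str, **kwargs) -> Optional[LocalHit]:
    hits = local_hits(query, target, **kwargs)
    return hits[0] if hits else None


def global_identity(a: str, b: str) -> float:
    """Identity of the end-to-end alignment: matches / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches, aln_len, _ = _parse_cigar(res["cigar"])
    return matches / aln_len if aln_len else 0.0


def six_frame_translate(seq: str) -> list[tuple[int, str]]:
    """All six translation frames as (frame, protein); internal stops kept.

    Frames 0..2 are the forward offsets, 3..5 the reverse-complement offsets.
    """
    frames = []
    rc = revcomp(seq)
    for off in range(3):
        for base, src in ((0, seq), (3, rc)):
            sub = src[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append((base + off, str(Seq(sub).translate())))
    return frames


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_DB_TOKEN_RE = re.compile(r"(db|superfamily|lineage):([^\s|]+)")


def parse_db_metadata(record: SequenceRecord) -> dict[str, str]:
    """Extract ``db:``, ``superfamily:``, ``lineage:`` tokens from a header id."""
    return {k: v for k, v in _DB_TOKEN_RE.findall(record.id)}


def _merged_query_coverage(hits: Sequence[LocalHit], qlen: int) -> float:
    iv = sorted((h.q_start, h.q_end) for h in hits)
    covered = 0
    cur_s, cur_e = iv[0]
    for s, e in iv[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / qlen


def seed_extend_align(
    query: SequenceRecord | str,
    db: Sequence[SequenceRecord],
    mode: str = "nucleotide",
    min_identity: Optional[float] = None,
    min_coverage: float = MIN_COVERAGE,
) -> list[AlignmentHit]:
    """Align a DNA query against a nucleotide or protein database.

    Returns one hit per database entry that passes the identity and
    coverage floors, sorted by score descending. ``mode='translated'``
    six-frame-translates the query and aligns against protein entries.
    """
    if isinstance(query, str):
        query = SequenceRecord(id="query", sequence=query)
    if mode not in {"nucleotide", "translated"}:
        raise ValueError(f"unknown mode {mode!r}")
    if min_identity is None:
        min_identity = MIN_IDENTITY_NUC if mode == "nucleotide" else MIN_IDENTITY_AA
    qseq = query.sequence
    out: list[AlignmentHit] = []
    if mode == "nucleotide":
        for rec in db:
            hits = local_hits(qseq, rec.sequence)
            if not hits:
                continue
            best = hits[0]
            cov = _merged_query_coverage(hits, len(qseq))
            if best.identity < min_identity or cov < min_coverage:
                continue
            meta = parse_db_metadata(rec)
            out.append(
                AlignmentHit(
                    query_id=query.id,
                    subject_id=rec.id,
                    db_tag=meta.get("db", "gene"),
                    identity=best.identity,
                    alignment_length=best.aln_len,
                    query_coverage=cov,
                    score=float(best.score),
                    mode=mode,
                    superfamily=meta.get("superfamily"),
                    lineage=meta.get("lineage"),
                )
            )
    else:
        aligner = _protein_aligner()
        frames = six_frame_translate(qseq)
        for rec in db:
            prot_idx = _seed_positions(rec.sequence, AA_SEED_K)
            best_tuple = None
            for _frame, prot in frames:
                seeded = any(
                    prot[i:i + AA_SEED_K] in prot_idx
                    for i in range(len(prot) - AA_SEED_K + 1)
                )
                if not seeded:
                    continue
                alns = aligner.align(prot, rec.sequence)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                counts = aln.counts()
                aln_len = counts.identities + counts.mismatches + counts.gaps
                if aln_len == 0:
                    continue
                identity = counts.identities / aln_len
                q_span_nt = 3 * (aln.aligned[0][-1][1] - aln.aligned[0][0][0])
                cov = min(1.0, q_span_nt / len(qseq))
                cand = (float(aln.score), identity, aln_len, cov)
                if best_tuple is None or cand[0] > best_tuple[0]:
                    best_tuple = cand
            if best_tuple is None:
                continue
            score, identity, aln_len, cov = best_tuple
            if identity < min_identity or cov < min_coverage:
                continue
            meta = parse_db_metadata(rec)
            out.append(
                AlignmentHit(
                    query_id=query.id,
                    subject_id=rec.id,
                    db_tag=meta.get("db", "gene"),
                    identity=identity,
                    alignment_length=aln_len,
                    query_coverage=cov,
                    score=score,
                    mode=mode,
                    superfamily=meta.get("superfamily"),
                    lineage=meta.get("lineage"),
                )
            )
    out.sort(key=lambda h: (-h.score, h.subject_id))
    return out


def map_reads_depth(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_identity: float = 0.95,
    seed_k: int = 15,
) -> dict[str, np.ndarray]:
    """Per-base read depth over each reference, best-hit-only placement.

    Each read is placed at its single best (lowest edit distance) location
    across all references; reads under the identity floor are unmapped.
    Multi-mapping reads therefore count exactly once.
    """
    indexes = [(_seed_positions(ref.sequence, seed_k), ref) for ref in references]
    depth = {ref.id: np.zeros(len(ref.sequence), dtype=np.int64) for ref in references}
    for read in reads:
        best = None  # (edit_distance, ref_ordinal, t_start, t_end)
        for variant in (read.sequence, revcomp(read.sequence)):
            max_ed = int(len(variant) * (1 - min_identity))
            seeds = {
                variant[i:i + seed_k]
                for i in range(0, len(variant) - seed_k + 1, seed_k)
            }
            for ref_i, (idx, ref) in enumerate(indexes):
                positions = sorted(
                    {t - i for i in range(0, len(variant) - seed_k + 1, seed_k)
                     for s in [variant[i:i + seed_k]] if s in idx for t in idx[s]}
                )
                if not positions:
                    continue
                pad = max_ed + 2
                windows = []
                for p in positions:
                    lo = max(0, p - pad)
                    hi = min(len(ref.sequence), p + len(variant) + pad)
                    if windows and lo <= windows[-1][1]:
                        windows[-1] = (windows[-1][0], hi)
                    else:
                        windows.append((lo, hi))
                for lo, hi in windows:
                    res = edlib.align(
                        variant, ref.sequence[lo:hi], mode="HW",
                        task="locations", k=max_ed,
                    )
                    ed = res["editDistance"]
                    if ed < 0:
                        continue
                    loc = res["locations"][0]
                    cand = (ed, ref_i, lo + loc[0], lo + loc[1] + 1)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            _ed, ref_i, t0, t1 = best
            depth[indexes[ref_i][1].id][t0:t1] += 1
    return depth
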