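"""End-to-end detection: reads in, clustered HT candidates out.

Wires the stages together: cross-species k-mer read screen, low-complexity
filtering, per-species assembly, annotation, ortholog HS baseline, RBH
pairing, candidate calling and clustering. Each stage is importable on its
own; this module only sequences them and carries the intermediate results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import kmers
from .annotate import ScaffoldAnnotation, annotate_scaffolds
from .assembly import Scaffold, assemble
from .candidates import (
    HTCandidate,
    OrthologBaseline,
    build_ortholog_baseline,
    call_candidates,
    cluster_candidates,
    rbh_pairs,
)
from .complexity import filter_low_complexity
from .config import RunConfig
from .io import SequenceRecord, write_candidate_report, write_fasta

logger = logging.getLogger("interchange")

__all__ = ["DetectionResult", "detect", "screen_reads"]


@dataclass
class DetectionResult:
    """All intermediate and final artifacts of one pairwise detection run."""

    retained_a: list[SequenceRecord]
    retained_b: list[SequenceRecord]
    scaffolds_a: list[Scaffold]
    scaffolds_b: list[Scaffold]
    annotations: dict[str, ScaffoldAnnotation]
    baseline: Optional[OrthologBaseline]
    hs_threshold: float
    rbh: list[tuple[Scaffold, Scaffold, float]]
    candidates: list[HTCandidate]

    @property
    def scaffold_sequences(self) -> dict[str, str]:
        return {s.id: s.sequence for s in [*self.scaffolds_a, *self.scaffolds_b]}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds_a, outdir / "scaffolds_a.fasta")
        write_fasta(self.scaffolds_b, outdir / "scaffolds_b.fasta")
        write_candidate_report(self.candidates, outdir / "candidates.tsv")


def _with_mates(retained: np.ndarray, n_reads: int, paired: bool) -> np.ndarray:
    """Extend a retained-read index set with the mates of retained reads.

    Reads are ordered first-mates then second-mates, so the mate of read i
    is i +/- n_reads/2. Keeping both mates preserves pairing information for
    assembly and bridges short gaps between retained blocks.
    """
    if not paired:
        return retained
    half = n_reads // 2
    mates = np.where(retained < half, retained + half, retained - half)
    return np.union1d(retained, mates)


def screen_reads(
    reads_a: Sequence[SequenceRecord],
    reads_b: Sequence[SequenceRecord],
    config: RunConfig,
    paired: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """k-mer homology screen + dust filter; returns retained reads per species.

    ``paired`` input must be ordered first-mates then second-mates per
    species; when either mate of a fragment is retained both are kept.

    Retention has two modes. ``per_read`` (default) scores each read by the
    merged span of its k-mers found anywhere in the other species' index,
    the natural reading of a k-mer search that reports query positions
    only. ``per_pair`` scores every cross-species read pair and requires
    min(S_a, S_b) >= threshold, a stricter variant that caps a read's score
    by its single best partner's reading frame.
    """
    if config.retention_mode == "per_read":
        ids_a, ids_b = kmers.retain_homologous_reads(
            reads_a, reads_b, config.k,
            config.read_similarity_threshold, config.min_kmer_occurrence,
        )
    else:
        index_a = kmers.build_kmer_index(
            reads_a, config.k, config.min_kmer_occurrence
        )
        hits = kmers.find_shared_hits(index_a, reads_b)
        logger.info("shared k-mer hits: %d", len(hits))
        lengths_b = np.asarray([len(r.sequence) for r in reads_b])
        scores = kmers.score_all_pairs(hits, index_a.read_lengths, lengths_b)
        ids_a, ids_b = kmers.retain_homologous_pairs(
            scores, config.read_similarity_threshold
        )
    logger.info("retained reads: %d (a) / %d (b)", len(ids_a), len(ids_b))
    ids_a = _with_mates(ids_a, len(reads_a), paired)
    ids_b = _with_mates(ids_b, len(reads_b), paired)
    kept_a = [reads_a[i] for i in ids_a.tolist()]
    kept_b = [reads_b[i] for i in ids_b.tolist()]
    kept_a, rej_a = filter_low_complexity(kept_a, config.dust_threshold)
    kept_b, rej_b = filter_low_complexity(kept_b, config.dust_threshold)
    if rej_a or rej_b:
        logger.info(
            "dust-rejected reads: %d (a) / %d (b): %s",
            len(rej_a), len(rej_b),
            [r.id for r in (rej_a + rej_b)[:10]],
        )
    return kept_a, kept_b


def detect(
    reads_a: Sequence[SequenceRecord],
    reads_b: Sequence[SequenceRecord],
    ortholog_pairs: Sequence[tuple[str, str]] | Sequence[float] = (),
    config: Optional[RunConfig] = None,
    species: tuple[str, str] = ("speciesA", "speciesB"),
    nucleotide_dbs: Sequence[SequenceRecord] = (),
    protein_dbs: Sequence[SequenceRecord] = (),
    hs_override: Optional[float] = None,
    paired: bool = True,
) -> DetectionResult:
    """Run the whole detection pipeline on two species' read sets.

    ``ortholog_pairs`` supplies the HS baseline (aligned ortholog sequence
    pairs, or precomputed percent identities); alternatively pass
    ``hs_override`` as a percent identity threshold.
    """
    config = config or RunConfig()
    kept_a, kept_b = screen_reads(reads_a, reads_b, config, paired=paired)
    scaffolds_a = assemble(kept_a, config.assembly_k, species=species[0])
    scaffolds_b = assemble(kept_b, config.assembly_k, species=species[1])
    logger.info(
        "scaffolds: %d (a, max %s bp) / %d (b, max %s bp)",
        len(scaffolds_a), scaffolds_a[0].length if scaffolds_a else 0,
        len(scaffolds_b), scaffolds_b[0].length if scaffolds_b else 0,
    )
    annotations = annotate_scaffolds(
        [*scaffolds_a, *scaffolds_b], nucleotide_dbs, protein_dbs
    )
    baseline = None
    if hs_override is not None:
        hs = hs_override
    else:
        baseline = build_ortholog_baseline(ortholog_pairs)
        hs = baseline.hs
    logger.info("HS threshold: %.2f%%", hs)
    candidates: list[HTCandidate] = []
    pairs: list[tuple[Scaffold, Scaffold, float]] = []
    if scaffolds_a and scaffolds_b:
        pairs = rbh_pairs(scaffolds_a, scaffolds_b)
        candidates = call_candidates(
            pairs, annotations, baseline if baseline is not None else hs,
            config.min_scaffold_length,
        )
        sequences = {s.id: s.sequence for s in [*scaffolds_a, *scaffolds_b]}
        candidates = cluster_candidates(
            candidates, sequences,
            config.cluster_identity_min, config.cluster_coverage_min,
        )
    return DetectionResult(
        retained_a=kept_a,
        retained_b=kept_b,
        scaffolds_a=scaffolds_a,
        scaffolds_b=scaffolds_b,
        annotations=annotations,
        baseline=baseline,
        hs_threshold=hs,
        rbh=pairs,
        candidates=candidates,
    )
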