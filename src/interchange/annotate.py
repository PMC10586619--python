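"""Scaffold classification and TE lineage profiling against reference databases.

Databases are FASTA files whose headers carry ``db:{gene|TE|MCR}`` and,
for TE proteins, optional ``superfamily:{Copia|Gypsy|...}`` and
``lineage:{Ale|Ivana|...}`` tokens. A scaffold takes the category of its
best-scoring hit; scaffolds matching mitochondrial/chloroplast/ribosomal
(MCR) sequences are flagged so candidate calling can exclude them — such
genes are conserved enough between distant species to mimic transfer.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentHit, seed_extend_align
from .io import SequenceRecord

__all__ = [
    "ScaffoldAnnotation",
    "LineageFrequencyTable",
    "classify_scaffold",
    "annotate_scaffolds",
    "profile_te_lineages",
]

_CATEGORY_PRIORITY = {"MCR": 2, "TE": 1, "gene": 0}


@dataclass(frozen=True)
class ScaffoldAnnotation:
    scaffold_id: str
    category: str  # gene | TE | MCR | unknown
    best_subject: Optional[str] = None
    superfamily: Optional[str] = None
    lineage: Optional[str] = None


def classify_scaffold(hits: Sequence[AlignmentHit]) -> ScaffoldAnnotation:
    """Category of the maximum-score hit; ``unknown`` when nothing passed.

    Ties on score are broken by higher identity, then by MCR > TE > gene so
    the MCR exclusion stays conservative. The result is a pure function of
    the hit set — hit order never matters.
    """
    if not hits:
        return ScaffoldAnnotation(scaffold_id="", category="unknown")
    best = max(
        hits,
        key=lambda h: (
            h.score,
            h.identity,
            _CATEGORY_PRIORITY.get(h.db_tag, -1),
            h.subject_id,  # total order for full determinism
        ),
    )
    return ScaffoldAnnotation(
        scaffold_id=best.query_id,
        category=best.db_tag,
        best_subject=best.subject_id,
        superfamily=best.superfamily,
        lineage=best.lineage,
    )


def annotate_scaffolds(
    scaffolds,
    nucleotide_dbs: Sequence[SequenceRecord] = (),
    protein_dbs: Sequence[SequenceRecord] = (),
) -> dict[str, ScaffoldAnnotation]:
    """Align every scaffold to the databases and classify it."""
    out: dict[str, ScaffoldAnnotation] = {}
    for sc in scaffolds:
        query = SequenceRecord(id=sc.id, sequence=sc.sequence)
        hits: list[AlignmentHit] = []
        if nucleotide_dbs:
            hits += seed_extend_align(query, nucleotide_dbs, "nucleotide")
        if protein_dbs:
            hits += seed_extend_align(query, protein_dbs, "translated")
        ann = classify_scaffold(hits)
        out[sc.id] = ScaffoldAnnotation(
            scaffold_id=sc.id,
            category=ann.category,
            best_subject=ann.best_subject,
            superfamily=ann.superfamily,
            lineage=ann.lineage,
        )
    return out


@dataclass
class LineageFrequencyTable:
    """Read counts and relative frequencies per TE superfamily and lineage.

    Frequencies are relative to the total number of aligned reads, so they
    sum to 1 whenever any read aligned.
    """

    superfamily_counts: dict[str, int]
    lineage_counts: dict[tuple[str, str], int]
    total_aligned: int

    @property
    def superfamily_frequencies(self) -> dict[str, float]:
        if self.total_aligned == 0:
            return {}
        return {k: v / self.total_aligned for k, v in self.superfamily_counts.items()}

    @property
    def lineage_frequencies(self) -> dict[tuple[str, str], float]:
        if self.total_aligned == 0:
            return {}
        return {k: v / self.total_aligned for k, v in self.lineage_counts.items()}


def profile_te_lineages(
    reads: Sequence[SequenceRecord],
    protein_db: Sequence[SequenceRecord],
) -> LineageFrequencyTable:
    """Tally reads by the TE lineage of their best protein hit.

    Each read counts at most once, toward its single best-scoring database
    protein; reads with no passing hit are ignored. With no aligned reads
    the table is empty rather than dividing by zero.
    """
    sup: dict[str, int] = defaultdict(int)
    lin: dict[tuple[str, str], int] = defaultdict(int)
    total = 0
    for read in reads:
        hits = seed_extend_align(read, protein_db, "translated")
        if not hits:
            continue
        best = hits[0]
        family = best.superfamily or "unclassified"
        lineage = best.lineage or "unclassified"
        sup[family] += 1
        lin[(family, lineage)] += 1
        total += 1
    return LineageFrequencyTable(dict(sup), dict(lin), total)
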