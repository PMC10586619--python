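"""Reading and writing of on-disk artifacts: FASTA/FASTQ, TSV reports, YAML config.

All sequence I/O goes through Biopython's SeqIO; gzip is handled
transparently by extension. Sequences are uppercased on load and restricted
to the DNA alphabet {A,C,G,T,N} (protein databases skip that check).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "load_sequences",
    "write_fasta",
    "write_fastq",
    "write_candidate_report",
    "read_candidate_report",
]

_DNA = set("ACGTN")

CANDIDATE_COLUMNS = [
    "cluster_id",
    "species_a",
    "species_b",
    "scaffold_a_id",
    "scaffold_b_id",
    "length_a",
    "length_b",
    "identity",
    "category",
    "HS_pass",
    "PI_pass",
    "PD_pass",
]


@dataclass
class SequenceRecord:
    """One sequence with optional FASTQ quality and a species label."""

    id: str
    sequence: str
    quality: Optional[str] = None
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".fna", ".ffn", ".faa", ".frn"}:
        return "fasta"
    # fall back to first character
    with _open_text(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def load_sequences(
    path: str | Path,
    format: str = "auto",
    species: str = "",
    alphabet_check: bool = True,
) -> list[SequenceRecord]:
    """Load FASTA or FASTQ (optionally gzipped) into SequenceRecord objects.

    Lowercase bases are uppercased; record order is preserved. An empty file
    yields an empty list. A malformed record raises ``ValueError`` naming the
    offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {format!r}")
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                seq = str(rec.seq).upper()
                qual = None
                if format == "fastq":
                    phred = rec.letter_annotations.get("phred_quality")
                    qual = "".join(chr(q + 33) for q in phred) if phred else None
                if alphabet_check and not set(seq) <= _DNA:
                    bad = sorted(set(seq) - _DNA)
                    raise ValueError(
                        f"record {rec.id!r} in {path}: non-DNA symbols {bad}"
                    )
                records.append(
                    SequenceRecord(id=rec.id, sequence=seq, quality=qual, species=species)
                )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fasta(records, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def write_candidate_report(candidates, path: str | Path) -> None:
    """Write HT candidates as TSV, sorted by identity desc then scaffold ids.

    One row per candidate; a header row is always present, so an empty
    candidate list yields a header-only file.
    """
    rows = sorted(
        candidates,
        key=lambda c: (-c.identity, c.scaffold_a_id, c.scaffold_b_id),
    )
    with open(path, "wt") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    [
                        str(c.cluster_id),
                        c.species_a,
                        c.species_b,
                        c.scaffold_a_id,
                        c.scaffold_b_id,
                        str(c.length_a),
                        str(c.length_b),
                        f"{c.identity:.4f}",
                        c.category,
                        _flag(c.HS_pass),
                        _flag(c.PI_pass),
                        _flag(c.PD_pass),
                    ]
                )
                + "\n"
            )


def _flag(value) -> str:
    if value is None:
        return "NA"
    return "1" if value else "0"


def _unflag(text: str):
    if text == "NA":
        return None
    return text == "1"


def read_candidate_report(path: str | Path):
    """Round-trip reader for :func:`write_candidate_report` output."""
    from .candidates import HTCandidate

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                HTCandidate(
                    scaffold_a_id=f[3],
                    scaffold_b_id=f[4],
                    species_a=f[1],
                    species_b=f[2],
                    length_a=int(f[5]),
                    length_b=int(f[6]),
                    identity=float(f[7]),
                    category=f[8],
                    HS_pass=_unflag(f[9]),
                    PI_pass=_unflag(f[10]),
                    PD_pass=_unflag(f[11]),
                    cluster_id=int(f[0]) if f[0] != "NA" else None,
                )
            )
    return out
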