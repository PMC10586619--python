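"""Synthetic horizontal-transfer benchmark: genomes, transfers, reads, scoring.

The generator emulates the published validation protocol: two genomes
descended from a common ancestor, gene and TE copies of one species
inserted into the other after mutation to a controlled identity (recent to
ancient transfers), and wgsim-style error-bearing 150 bp paired-end reads
at 20X with ~350 bp inserts. A truth table records every simulated event so
detection output can be scored for recall and false positives.

Coordinates are 0-based half-open in memory; truth tables are written
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import local_hits
from .assembly import revcomp
from .io import SequenceRecord

__all__ = [
    "Feature",
    "SyntheticGenome",
    "TruthRecord",
    "EvaluationResult",
    "generate_genome_pair",
    "mutate_to_identity",
    "insert_transfers",
    "simulate_reads",
    "evaluate_calls",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
DEFAULT_TE_MIX = (
    ("Copia", "Ale"),
    ("Copia", "Ivana"),
    ("Copia", "Tork"),
    ("Gypsy", "Athila"),
    ("Gypsy", "Tekay"),
)


@dataclass(frozen=True)
class Feature:
    id: str
    type: str  # gene | TE
    start: int
    end: int
    strand: str = "+"
    superfamily: Optional[str] = None
    lineage: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticGenome:
    species: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def feature_sequence(self, feat: Feature) -> str:
        seq = self.sequence[feat.start:feat.end]
        return seq if feat.strand == "+" else revcomp(seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TruthRecord:
    """One simulated transfer event and where it landed."""

    event_id: str
    donor: str
    recipient: str
    source_feature: str
    start: int  # 0-based half-open in the final recipient sequence
    end: int
    target_identity: float
    realized_identity: float
    type: str  # gene | TE
    sequence: str = ""  # the inserted (mutated) copy


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _random_gene(rng: np.random.Generator, length: int) -> str:
    """An ORF-bearing sequence: ATG, stop-free codons, terminal TAA."""
    n_codons = max(4, length // 3)
    body = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons - 2))
    return "ATG" + body + "TAA"


def _random_te(rng: np.random.Generator, length: int) -> str:
    """An LTR-retrotransposon-like sequence: identical terminal repeats."""
    ltr_len = int(rng.integers(200, min(501, length // 3)))
    ltr = _random_dna(rng, ltr_len)
    internal = _random_dna(rng, length - 2 * ltr_len)
    return ltr + internal + ltr


def generate_genome_pair(
    length: int,
    divergence: float,
    n_genes: int,
    n_tes: int,
    seed: int,
    species: tuple[str, str] = ("speciesA", "speciesB"),
    gene_length: tuple[int, int] = (1000, 3000),
    te_length: tuple[int, int] = (2000, 8000),
    te_mix: Sequence[tuple[str, str]] = DEFAULT_TE_MIX,
) -> tuple[SyntheticGenome, SyntheticGenome]:
    """Two genomes descended from a shared ancestor with planted features.

    An ancestral sequence of uniform base composition carries ``n_genes``
    ORF-bearing genes and ``n_tes`` LTR-structured TEs at random
    non-overlapping positions. The descendants each substitute at rate
    divergence/2 (disjoint position sets, so their pairwise identity is
    1 - divergence by construction and the feature coordinates lift over
    unchanged).
    """
    if not (0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    feats: list[tuple[str, str, Optional[str], Optional[str]]] = []
    for i in range(n_genes):
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        feats.append((f"gene_{i + 1}", _random_gene(rng, glen), None, None))
    for i in range(n_tes):
        tlen = int(rng.integers(te_length[0], te_length[1] + 1))
        fam, lin = te_mix[i % len(te_mix)]
        feats.append((f"te_{i + 1}", _random_te(rng, tlen), fam, lin))
    total_feat = sum(len(s) for _, s, _, _ in feats)
    if total_feat > 0.8 * length:
        raise ValueError(
            f"features ({total_feat} bp) do not fit in {length} bp genome"
        )
    # split the remaining length into random spacers between features
    spacer_total = length - total_feat
    cuts = np.sort(rng.integers(0, spacer_total + 1, len(feats)))
    spacers = np.diff(np.concatenate([[0], cuts, [spacer_total]]))
    order = rng.permutation(len(feats))
    pieces = []
    features: list[Feature] = []
    pos = 0
    for slot, fi in enumerate(order):
        gap = int(spacers[slot])
        pieces.append(_random_dna(rng, gap))
        pos += gap
        fid, fseq, fam, lin = feats[fi]
        ftype = "gene" if fid.startswith("gene") else "TE"
        features.append(
            Feature(fid, ftype, pos, pos + len(fseq), "+", fam, lin)
        )
        pieces.append(fseq)
        pos += len(fseq)
    pieces.append(_random_dna(rng, int(spacers[-1])))
    ancestor = "".join(pieces)
    assert len(ancestor) == length

    codes = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()
    n_diff = round(length * divergence)
    diff_pos = rng.choice(length, size=n_diff, replace=False)
    half = n_diff // 2
    seq_a = _substitute(codes.copy(), diff_pos[:half], rng)
    seq_b = _substitute(codes.copy(), diff_pos[half:], rng)
    features.sort(key=lambda f: f.start)
    return (
        SyntheticGenome(species[0], seq_a.tobytes().decode(), list(features)),
        SyntheticGenome(species[1], seq_b.tobytes().decode(), list(features)),
    )


_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def _substitute(codes: np.ndarray, positions: np.ndarray, rng) -> np.ndarray:
    """Substitute each position to a uniformly chosen *different* base."""
    if len(positions) == 0:
        return codes
    old = _BASE_TO_IDX[codes[positions]]
    shift = rng.integers(1, 4, len(positions))
    codes[positions] = _BASES[(old + shift) % 4]
    return codes


def mutate_to_identity(sequence: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Substitute exactly round((1 - identity) * L) distinct positions.

    No indels are introduced, so a direct positionwise comparison of input
    and output realizes the target identity to within 1/L.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(sequence)
    n_mut = round((1 - target_identity) * L)
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    positions = rng.choice(L, size=n_mut, replace=False)
    return _substitute(codes, positions, rng).tobytes().decode()


def insert_transfers(
    donor: SyntheticGenome,
    recipient: SyntheticGenome,
    n_genes: int,
    n_tes: int,
    identity_range: tuple[float, float] = (0.80, 1.00),
    seed: int = 0,
    min_feature_length: int = 0,
) -> tuple[SyntheticGenome, list[TruthRecord]]:
    """Copy donor features into the recipient at controlled divergence.

    Sampled features are mutated to a target identity drawn uniformly from
    ``identity_range`` and spliced at random positions outside existing
    recipient features. Returns the modified recipient (its feature table
    updated and shifted) and the truth table.
    """
    rng = np.random.default_rng(seed)
    pool_genes = [f for f in donor.features
                  if f.type == "gene" and f.length >= min_feature_length]
    pool_tes = [f for f in donor.features
                if f.type == "TE" and f.length >= min_feature_length]
    if len(pool_genes) < n_genes or len(pool_tes) < n_tes:
        raise ValueError(
            f"donor has {len(pool_genes)} genes / {len(pool_tes)} TEs of the "
            f"required length; asked for {n_genes} / {n_tes}"
        )
    chosen = [pool_genes[i] for i in rng.choice(len(pool_genes), n_genes, replace=False)]
    chosen += [pool_tes[i] for i in rng.choice(len(pool_tes), n_tes, replace=False)]

    occupied = np.zeros(len(recipient.sequence) + 1, dtype=bool)
    for f in recipient.features:
        occupied[f.start + 1:f.end] = True  # insertion allowed at boundaries
    free = np.nonzero(~occupied)[0]
    sites = np.sort(rng.choice(free, size=len(chosen), replace=False))
    site_order = rng.permutation(len(chosen))

    inserts = []
    for site, fi in zip(sites, site_order):
        feat = chosen[fi]
        lo, hi = identity_range
        target = float(rng.uniform(lo, hi))
        src = donor.feature_sequence(feat)
        mutated = mutate_to_identity(src, target, rng)
        realized = 1 - sum(a != b for a, b in zip(src, mutated)) / len(src)
        inserts.append((int(site), feat, target, realized, mutated))

    new_seq_parts = []
    new_features: list[Feature] = []
    truth: list[TruthRecord] = []
    prev = 0
    shift = 0
    pending = sorted(recipient.features, key=lambda f: f.start)
    for k, (site, feat, target, realized, mutated) in enumerate(inserts):
        new_seq_parts.append(recipient.sequence[prev:site])
        start = site + shift
        end = start + len(mutated)
        event_id = f"ht_{k + 1}"
        new_features.append(
            Feature(event_id, feat.type, start, end, "+",
                    feat.superfamily, feat.lineage)
        )
        truth.append(
            TruthRecord(
                event_id=event_id,
                donor=donor.species,
                recipient=recipient.species,
                source_feature=feat.id,
                start=start,
                end=end,
                target_identity=target,
                realized_identity=realized,
                type=feat.type,
                sequence=mutated,
            )
        )
        new_seq_parts.append(mutated)
        shift += len(mutated)
        prev = site
    new_seq_parts.append(recipient.sequence[prev:])
    new_sequence = "".join(new_seq_parts)

    site_arr = np.array([s for s, *_ in inserts])
    len_arr = np.array([len(m) for *_, m in inserts])
    for f in pending:
        off = int(len_arr[site_arr <= f.start].sum())
        new_features.append(replace(f, start=f.start + off, end=f.end + off))
    new_features.sort(key=lambda f: f.start)
    out = SyntheticGenome(recipient.species, new_sequence, new_features)
    return out, truth


def simulate_reads(
    genome: SyntheticGenome | str,
    read_length: int = 150,
    coverage: float = 20.0,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    base_error_rate: float = 0.02,
    seed: int = 0,
    species: str = "",
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """wgsim-style paired-end reads: uniform fragments, normal insert sizes.

    Fragment (insert) lengths follow Normal(insert_mean, insert_sd)
    truncated below at 2 * read_length; mate 2 is the reverse complement of
    the fragment end; sequencing errors are uniform substitutions at
    ``base_error_rate``; qualities are constant Q30. The pair count is
    coverage * genome_length / (2 * read_length).
    """
    seq = genome.sequence if isinstance(genome, SyntheticGenome) else genome
    sp = species or (genome.species if isinstance(genome, SyntheticGenome) else "sim")
    L = len(seq)
    if L <= insert_mean + 4 * insert_sd:
        raise ValueError("genome too short for the requested insert size")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_length)))
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    inserts = np.maximum(
        2 * read_length,
        np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(np.int64),
    )
    inserts = np.minimum(inserts, L)
    starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5
    reads1, reads2 = [], []
    qual = chr(30 + 33) * read_length
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        fwd = codes[s:s + read_length]
        rev = codes[s + ins - read_length:s + ins]
        r1 = fwd.tobytes().decode()
        r2 = revcomp(rev.tobytes().decode())
        if flip[i]:
            r1, r2 = revcomp(r2), revcomp(r1)
        if base_error_rate > 0:
            r1 = _inject_errors(r1, base_error_rate, rng)
            r2 = _inject_errors(r2, base_error_rate, rng)
        name = f"{sp}_read{i + 1}"
        reads1.append(SequenceRecord(f"{name}/1", r1, qual, sp))
        reads2.append(SequenceRecord(f"{name}/2", r2, qual, sp))
    return reads1, reads2


def _inject_errors(read: str, rate: float, rng) -> str:
    codes = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(codes)) < rate
    positions = np.nonzero(mask)[0]
    if len(positions) == 0:
        return read
    return _substitute(codes, positions, rng).tobytes().decode()


@dataclass
class EvaluationResult:
    """Detection performance against the simulated truth."""

    n_truth: int
    n_matched: int
    false_positives: int
    matched_events: list[str]
    by_type: dict[str, tuple[int, int]]  # type -> (matched, total)
    curve: list[tuple[int, int, int]]  # (length filter, TP, FP)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0


def evaluate_calls(
    candidates,
    truth: Sequence[TruthRecord],
    scaffold_sequences: dict[str, str],
    match_identity: float = 0.80,
    match_coverage: float = 0.50,
    length_filters: Sequence[int] = (0, 500, 1000, 1500, 2000),
) -> EvaluationResult:
    """Score candidates against the truth table.

    A truth event is recovered when the candidate scaffolds'
    >= ``match_identity`` alignments collectively cover
    >= ``match_coverage`` of its inserted copy. A candidate is a false
    positive when none of its alignments to any inserted copy covers
    ``match_coverage`` of the copy or of the candidate's own scaffold —
    i.e. when the candidate is not substantially made of transferred
    sequence. The curve reports TP/FP with the minimum-scaffold-length
    filter swept.
    """
    if not truth:
        raise ValueError("truth table is empty")
    cand_scaffolds = {}
    for c in candidates:
        for sid in (c.scaffold_a_id, c.scaffold_b_id):
            seq = scaffold_sequences.get(sid)
            if seq:
                cand_scaffolds.setdefault(sid, seq)

    # per (truth, candidate): does any scaffold of the candidate hit the copy?
    cand_match: dict[int, set[str]] = {i: set() for i in range(len(candidates))}
    event_cover: dict[str, list[tuple[int, int]]] = {t.event_id: [] for t in truth}
    for t in truth:
        for ci, c in enumerate(candidates):
            for sid in (c.scaffold_a_id, c.scaffold_b_id):
                seq = cand_scaffolds.get(sid)
                if not seq:
                    continue
                hits = [
                    h for h in local_hits(t.sequence, seq)
                    if h.identity >= match_identity
                ]
                if not hits:
                    continue
                covered = sum(h.q_end - h.q_start for h in hits)
                event_cover[t.event_id].extend(
                    (ci, h.q_start, h.q_end) for h in hits
                )
                if (covered >= match_coverage * len(t.sequence)
                        or covered >= match_coverage * len(seq)):
                    cand_match[ci].add(t.event_id)

    def _merged(iv: list[tuple[int, int]]) -> int:
        if not iv:
            return 0
        iv = sorted(iv)
        tot, cs, ce = 0, *iv[0]
        for s, e in iv[1:]:
            if s > ce:
                tot += ce - cs
                cs, ce = s, e
            else:
                ce = max(ce, e)
        return tot + (ce - cs)

    def _matched_events(keep: set[int]) -> set[str]:
        out = set()
        for t in truth:
            iv = [(s, e) for ci, s, e in event_cover[t.event_id] if ci in keep]
            if _merged(iv) >= match_coverage * len(t.sequence):
                out.add(t.event_id)
        return out

    all_ci = set(range(len(candidates)))
    matched_set = _matched_events(all_ci)
    matched = [t.event_id for t in truth if t.event_id in matched_set]
    fp = sum(1 for ci in all_ci if not cand_match[ci])
    by_type: dict[str, tuple[int, int]] = {}
    for ttype in sorted({t.type for t in truth}):
        tot = sum(1 for t in truth if t.type == ttype)
        got = sum(1 for t in truth if t.type == ttype and t.event_id in matched_set)
        by_type[ttype] = (got, tot)

    curve = []
    for lf in length_filters:
        keep = {ci for ci, c in enumerate(candidates)
                if min(c.length_a, c.length_b) >= lf}
        tp_events = _matched_events(keep)
        fp_n = sum(1 for ci in keep if not cand_match[ci])
        curve.append((lf, len(tp_events), fp_n))

    return EvaluationResult(
        n_truth=len(truth),
        n_matched=len(matched),
        false_positives=fp,
        matched_events=matched,
        by_type=by_type,
        curve=curve,
    )


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    """TSV truth table with 1-based inclusive coordinates."""
    cols = ["event_id", "donor", "recipient", "source_feature", "start", "end",
            "target_identity", "realized_identity", "type"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write(
                f"{t.event_id}\t{t.donor}\t{t.recipient}\t{t.source_feature}\t"
                f"{t.start + 1}\t{t.end}\t{t.target_identity:.4f}\t"
                f"{t.realized_identity:.4f}\t{t.type}\n"
            )
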