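"""HT candidate calling: ortholog identity baseline, RBH pairing, clustering.

The high-similarity (HS) threshold is derived from the distribution of
orthologous gene identities between the two compared species:

    HS = Q3 + IQR / 2,   IQR = Q3 - Q1,

with quartiles taken by linear interpolation on the sorted sample (the
convention placing the q-th quantile at rank (n-1)q). A reciprocal-best-hit
scaffold pair whose alignment identity reaches HS, whose two scaffolds both
reach the minimum length (1 kb by default, which removes most short
conserved-gene false positives), and which is not mitochondrial/
chloroplast/ribosomal becomes an HT candidate. Candidates are then
single-linkage clustered to collapse paralogous copies of the same element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import networkx as nx

from .align import LocalHit, best_local_alignment, global_identity
from .annotate import ScaffoldAnnotation
from .assembly import Scaffold
from .io import SequenceRecord

__all__ = [
    "OrthologBaseline",
    "HTCandidate",
    "build_ortholog_baseline",
    "rbh_pairs",
    "call_candidates",
    "cluster_candidates",
]


@dataclass(frozen=True)
class OrthologBaseline:
    """Ortholog percent-identity distribution and the HS threshold it yields."""

    identities: tuple[float, ...]
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def hs(self) -> float:
        return self.q3 + self.iqr / 2

    @property
    def n(self) -> int:
        return len(self.identities)


def build_ortholog_baseline(
    ortholog_pairs: Sequence[tuple[str, str]] | Sequence[float],
) -> OrthologBaseline:
    """Baseline from aligned ortholog pairs (or precomputed % identities).

    Each (sequence_a, sequence_b) pair is globally aligned and its percent
    identity added to the sample; at least 4 orthologs are required for the
    quartiles to be meaningful.
    """
    identities: list[float] = []
    for item in ortholog_pairs:
        if isinstance(item, (int, float)):
            identities.append(float(item))
        else:
            a, b = item
            identities.append(100.0 * global_identity(a, b))
    if len(identities) < 4:
        raise ValueError(
            "need >= 4 ortholog identities to compute quartiles; "
            "supply a manual HS threshold instead"
        )
    if not all(0 <= x <= 100 for x in identities):
        raise ValueError("identities must be percentages in [0, 100]")
    q1, q3 = np.quantile(identities, [0.25, 0.75])  # linear interpolation
    return OrthologBaseline(tuple(identities), float(q1), float(q3))


@dataclass
class HTCandidate:
    """A reciprocal-best-hit scaffold pair proposed as a horizontal transfer."""

    scaffold_a_id: str
    scaffold_b_id: str
    species_a: str
    species_b: str
    length_a: int
    length_b: int
    identity: float  # percent identity of the reciprocal best alignment
    category: str = "unknown"
    HS_pass: Optional[bool] = None
    PI_pass: Optional[bool] = None
    PD_pass: Optional[bool] = None
    cluster_id: Optional[int] = None


def rbh_pairs(
    scaffolds_a: Sequence[Scaffold],
    scaffolds_b: Sequence[Scaffold],
    aligner: Callable[[str, str], Optional[LocalHit]] = best_local_alignment,
) -> list[tuple[Scaffold, Scaffold, float]]:
    """Reciprocal best-hit scaffold pairs with their alignment identity.

    (a, b) is emitted iff b is a's unique best-scoring hit among B and a is
    b's unique best-scoring hit among A. Score ties for a best hit make the
    hit ambiguous (paralogy) and the scaffold forms no pair.
    """
    if not scaffolds_a or not scaffolds_b:
        raise ValueError("both scaffold sets must be non-empty")
    score: dict[tuple[int, int], LocalHit] = {}
    for i, sa in enumerate(scaffolds_a):
        for j, sb in enumerate(scaffolds_b):
            hit = aligner(sa.sequence, sb.sequence)
            if hit is not None:
                score[(i, j)] = hit

    def _unique_best(items: list[tuple[int, LocalHit]]) -> Optional[int]:
        if not items:
            return None
        best_score = max(h.score for _, h in items)
        winners = [k for k, h in items if h.score == best_score]
        return winners[0] if len(winners) == 1 else None

    best_of_a = {
        i: _unique_best([(j, h) for (ii, j), h in score.items() if ii == i])
        for i in range(len(scaffolds_a))
    }
    best_of_b = {
        j: _unique_best([(i, h) for (i, jj), h in score.items() if jj == j])
        for j in range(len(scaffolds_b))
    }
    pairs = []
    for i, j in sorted(k for k in score):
        if best_of_a.get(i) == j and best_of_b.get(j) == i:
            hit = score[(i, j)]
            pairs.append((scaffolds_a[i], scaffolds_b[j], 100.0 * hit.identity))
    return pairs


def call_candidates(
    pairs: Sequence[tuple[Scaffold, Scaffold, float]],
    annotations: dict[str, ScaffoldAnnotation],
    baseline: OrthologBaseline | float,
    min_scaffold_length: int = 1000,
) -> list[HTCandidate]:
    """Keep RBH pairs meeting the HS criterion.

    A pair survives iff identity >= HS (boundary inclusive), both scaffolds
    are at least ``min_scaffold_length``, and the pair is not classified as
    MCR. PI/PD flags start unset; the post-screen fills them.
    """
    hs = baseline.hs if isinstance(baseline, OrthologBaseline) else float(baseline)
    out = []
    for sa, sb, identity in pairs:
        cat_a = annotations.get(sa.id)
        cat_b = annotations.get(sb.id)
        category = _reconcile_category(cat_a, cat_b)
        if category == "MCR":
            continue
        if min(sa.length, sb.length) < min_scaffold_length:
            continue
        if identity < hs:
            continue
        out.append(
            HTCandidate(
                scaffold_a_id=sa.id,
                scaffold_b_id=sb.id,
                species_a=sa.species,
                species_b=sb.species,
                length_a=sa.length,
                length_b=sb.length,
                identity=identity,
                category=category,
                HS_pass=True,
            )
        )
    return out


def _reconcile_category(
    a: Optional[ScaffoldAnnotation], b: Optional[ScaffoldAnnotation]
) -> str:
    cats = {ann.category for ann in (a, b) if ann is not None}
    if "MCR" in cats:
        return "MCR"  # conservative: one MCR call excludes the pair
    for cat in ("TE", "gene"):
        if cat in cats:
            return cat
    return "unknown"


def cluster_candidates(
    candidates: Sequence[HTCandidate],
    sequences: dict[str, str],
    identity_min: float = 0.80,
    coverage_min: float = 0.80,
) -> list[HTCandidate]:
    """Single-linkage clustering of candidates via their scaffold sequences.

    Two candidates are linked when any scaffold of one aligns to any
    scaffold of the other at >= identity_min over >= coverage_min of the
    shorter sequence; connected components become clusters. Cluster ids are
    assigned in order of each cluster's first candidate.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if _linked(candidates[i], candidates[j], sequences,
                       identity_min, coverage_min):
                g.add_edge(i, j)
    comp_of = {}
    next_id = 1
    for i in range(len(candidates)):
        if i in comp_of:
            continue
        for member in nx.node_connected_component(g, i):
            comp_of[member] = next_id
        next_id += 1
    for i, cand in enumerate(candidates):
        cand.cluster_id = comp_of[i]
    return list(candidates)


def _linked(c1: HTCandidate, c2: HTCandidate, sequences, identity_min, coverage_min):
    ids1 = (c1.scaffold_a_id, c1.scaffold_b_id)
    ids2 = (c2.scaffold_a_id, c2.scaffold_b_id)
    for id1 in ids1:
        for id2 in ids2:
            s1, s2 = sequences.get(id1), sequences.get(id2)
            if s1 is None or s2 is None:
                continue
            short, long_ = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
            hit = best_local_alignment(short, long_)
            if hit is None:
                continue
            coverage = (hit.q_end - hit.q_start) / len(short)
            if hit.identity >= identity_min and coverage >= coverage_min:
                return True
    return False
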