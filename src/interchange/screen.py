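"""Post-candidate screening: phylogenetic incongruence, patchy distribution,
copy number from read depth, and transfer-age dating.

Two criteria complement high similarity. Phylogenetic incongruence (PI):
in the tree built from the transferred element the donor and recipient
come out as sister taxa although they are not sisters in the species tree.
Patchy distribution (PD): the element is present in the two partners (and
possibly species close to either) but missing from species closely related
to one of the partners — vertical inheritance would not produce such holes.

Copy number is estimated from unassembled reads as MCT / MCB: the median
per-base depth over the element divided by the median depth over
single-copy (BUSCO-style) genes. Transfer age uses the Ma & Bennetzen
molecular clock: T = (1 - identity) / (2 * rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .align import local_hits, map_reads_depth
from .io import SequenceRecord

__all__ = [
    "HomologyCriteria",
    "PresenceAbsenceMatrix",
    "CopyNumberEstimate",
    "AgeEstimate",
    "presence_absence",
    "pi_test",
    "pd_test",
    "nj_tree",
    "copy_number",
    "age_estimate",
]


@dataclass(frozen=True)
class HomologyCriteria:
    """Thresholds for calling an element present in a panel genome."""

    identity_min: float = 0.80
    coverage_min: float = 0.60

    def __post_init__(self) -> None:
        for v in (self.identity_min, self.coverage_min):
            if not (0 < v <= 1):
                raise ValueError("criteria must be in (0, 1]")


@dataclass
class PresenceAbsenceMatrix:
    """Presence of candidate elements across a genome panel."""

    species: list[str]
    elements: list[str]
    cells: dict[tuple[str, str], tuple[float, float]]  # present -> (identity, coverage)

    def is_present(self, species: str, element: str) -> bool:
        return (species, element) in self.cells

    def present_species(self, element: str) -> list[str]:
        return [s for s in self.species if (s, element) in self.cells]


def presence_absence(
    elements: Sequence[SequenceRecord],
    genome_panel: Sequence[SequenceRecord],
    criteria: HomologyCriteria = HomologyCriteria(),
) -> PresenceAbsenceMatrix:
    """Scan each element against each panel genome.

    An element is present in a genome when its hits at
    >= ``identity_min`` cover (after interval merging on the element)
    >= ``coverage_min`` of the element.
    """
    if not genome_panel:
        raise ValueError("genome panel must be non-empty")
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    for genome in genome_panel:
        for elem in elements:
            hits = [
                h for h in local_hits(elem.sequence, genome.sequence)
                if h.identity >= criteria.identity_min
            ]
            if not hits:
                continue
            iv = sorted((h.q_start, h.q_end) for h in hits)
            covered, (cs, ce) = 0, iv[0]
            for s, e in iv[1:]:
                if s > ce:
                    covered += ce - cs
                    cs, ce = s, e
                else:
                    ce = max(ce, e)
            covered += ce - cs
            coverage = covered / len(elem.sequence)
            if coverage >= criteria.coverage_min:
                best_identity = max(h.identity for h in hits)
                cells[(genome.id, elem.id)] = (best_identity, coverage)
    return PresenceAbsenceMatrix(
        species=[g.id for g in genome_panel],
        elements=[e.id for e in elements],
        cells=cells,
    )


def _load_tree(newick: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(newick, dendropy.Tree):
        return newick
    return dendropy.Tree.get(data=newick, schema="newick")


def _clade_leaves(tree: dendropy.Tree, a: str, b: str, name: str) -> set[str]:
    """Leaf set of the smallest clade containing both species (tree read as
    rooted at the seed node)."""
    labels = {t.label for t in tree.taxon_namespace}
    for sp in (a, b):
        if sp not in labels:
            raise ValueError(f"species {sp!r} missing from the {name} tree")
    best: set[str] | None = None
    for node in tree.postorder_node_iter():
        leaves = {leaf.taxon.label for leaf in node.leaf_iter()}
        if a in leaves and b in leaves and (best is None or len(leaves) < len(best)):
            best = leaves
    assert best is not None
    return best


def pi_test(
    candidate_tree: str | dendropy.Tree,
    species_tree: str | dendropy.Tree,
    species_a: str,
    species_b: str,
) -> tuple[bool, dict]:
    """Phylogenetic incongruence: sisters in the element tree, not in the
    species tree.

    True iff the smallest clade containing the two partners in the
    candidate tree holds no other taxon while in the species tree it does.
    A multifurcating candidate clade containing extra taxa is not a sister
    relation and fails.
    """
    cand = _load_tree(candidate_tree)
    spec = _load_tree(species_tree)
    cand_clade = _clade_leaves(cand, species_a, species_b, "candidate")
    spec_clade = _clade_leaves(spec, species_a, species_b, "species")
    sisters_in_candidate = cand_clade == {species_a, species_b}
    sisters_in_species = spec_clade == {species_a, species_b}
    result = sisters_in_candidate and not sisters_in_species
    report = {
        "candidate_clade": sorted(cand_clade),
        "species_clade": sorted(spec_clade),
        "sisters_in_candidate": sisters_in_candidate,
        "sisters_in_species": sisters_in_species,
    }
    return result, report


def _tree_distances(tree: dendropy.Tree):
    """Pairwise leaf distances: patristic if branch lengths exist, else edge counts."""
    pdm = tree.phylogenetic_distance_matrix()
    has_lengths = any(
        e.length is not None and e.length > 0 for e in tree.preorder_edge_iter()
    )

    def dist(x: str, y: str) -> float:
        tx = tree.taxon_namespace.get_taxon(x)
        ty = tree.taxon_namespace.get_taxon(y)
        if has_lengths:
            return pdm.patristic_distance(tx, ty)
        return pdm.path_edge_count(tx, ty)

    return dist


def pd_test(
    matrix: PresenceAbsenceMatrix,
    species_tree: str | dendropy.Tree,
    species_a: str,
    species_b: str,
    element: Optional[str] = None,
) -> tuple[bool, dict]:
    """Patchy distribution of one element across the panel phylogeny.

    True iff (i) the element is present only in the two partner species, or
    (ii) some panel species closer to one partner than the partners are to
    each other lacks the element.
    """
    if element is None:
        if len(matrix.elements) != 1:
            raise ValueError("element must be named when the matrix has several")
        element = matrix.elements[0]
    tree = _load_tree(species_tree)
    tree_labels = {t.label for t in tree.taxon_namespace}
    present = set(matrix.present_species(element)) | {species_a, species_b}
    if present == {species_a, species_b}:
        return True, {"mode": "only_partners", "present": sorted(present)}
    dist = _tree_distances(tree)
    d_ab = dist(species_a, species_b)
    holes = []
    for sp in matrix.species:
        if sp in (species_a, species_b) or sp not in tree_labels:
            continue
        close = min(dist(sp, species_a), dist(sp, species_b)) < d_ab
        if close and sp not in present:
            holes.append(sp)
    report = {
        "mode": "close_relative_lacks" if holes else "continuous",
        "present": sorted(present),
        "missing_close_relatives": holes,
        "partner_distance": d_ab,
    }
    return bool(holes), report


def nj_tree(
    distance_matrix: np.ndarray | Sequence[Sequence[float]],
    taxa: Sequence[str],
) -> str:
    """Neighbor-joining tree (Newick, unrooted) from a distance matrix.

    Ties in the Q criterion are broken by taxon label order, so the
    topology is deterministic under permutation of the input.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = len(taxa)
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match the taxon list")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # work on label-sorted order for deterministic tie-breaking
    order = sorted(range(n), key=lambda i: taxa[i])
    labels = [taxa[i] for i in order]
    d = d[np.ix_(order, order)]
    nodes = [f"{lab}" for lab in labels]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_node = n
    newick = {i: nodes[i] for i in range(n)}

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist[(i, j)] - r[i] - r[j]
                key = (q, newick[i], newick[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)) if m > 2 else dij / 2
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_node
        next_node += 1
        newick[u] = f"({newick[i]}:{li:.6f},{newick[j]}:{lj:.6f})"
        for kk in active:
            if kk in (i, j):
                continue
            duk = 0.5 * (dist[(i, kk)] + dist[(j, kk)] - dij)
            dist[(u, kk)] = dist[(kk, u)] = max(duk, 0.0)
        dist[(u, u)] = 0.0
        active = [x for x in active if x not in (i, j)] + [u]

    i, j = active
    return f"({newick[i]}:{dist[(i, j)] / 2:.6f},{newick[j]}:{dist[(i, j)] / 2:.6f});"


@dataclass(frozen=True)
class CopyNumberEstimate:
    element_id: str
    mct: float  # median per-base depth over the element
    mcb: float  # median over genes of each gene's median depth

    @property
    def copy_number(self) -> float:
        return self.mct / self.mcb


def copy_number(
    element: SequenceRecord,
    reads: Sequence[SequenceRecord],
    busco_genes: Sequence[SequenceRecord],
    min_identity: float = 0.95,
) -> CopyNumberEstimate:
    """Depth-ratio copy number of one element.

    Reads are placed best-hit-only at >= ``min_identity``; MCT is the
    median depth over the element, MCB the median across genes of each
    gene's median depth.
    """
    if not busco_genes:
        raise ValueError("need at least one single-copy gene")
    refs = [element, *busco_genes]
    depth = map_reads_depth(reads, refs, min_identity=min_identity)
    mct = float(np.median(depth[element.id]))
    gene_medians = [float(np.median(depth[g.id])) for g in busco_genes]
    mcb = float(np.median(gene_medians))
    if mcb == 0:
        raise ValueError("single-copy genes have zero depth; estimate undefined")
    return CopyNumberEstimate(element.id, mct, mcb)


@dataclass(frozen=True)
class AgeEstimate:
    identity: float
    clock_rate: float  # substitutions / site / year

    @property
    def years(self) -> float:
        return (1 - self.identity) / (2 * self.clock_rate)

    @property
    def mya(self) -> float:
        return round(self.years / 1e6, 2)


def age_estimate(identity: float, clock_rate: float = 1.3e-8) -> AgeEstimate:
    """Date a transfer from the partners' sequence identity.

    T = (1 - p) / (2r) with p the identity fraction and r the molecular
    clock rate; raw p-distance, no multiple-hit correction.
    """
    if not (0 < identity <= 1):
        raise ValueError("identity must be in (0, 1]")
    if clock_rate <= 0:
        raise ValueError("clock_rate must be positive")
    return AgeEstimate(identity, clock_rate)
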