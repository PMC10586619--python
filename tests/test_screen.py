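"""PI/PD criteria, neighbor joining, copy number and transfer dating."""

import subprocess

import dendropy
import numpy as np
import pytest

from interchange.io import SequenceRecord
from interchange.screen import (
    HomologyCriteria,
    age_estimate,
    copy_number,
    nj_tree,
    pd_test,
    pi_test,
    presence_absence,
)
from interchange.simulate import mutate_to_identity, simulate_reads, _random_gene, _random_te

from conftest import random_dna


# ---------------------------------------------------------------- presence/absence

def test_exact_copy_is_present(rng):
    elem = SequenceRecord("el", random_dna(rng, 1000))
    genome = SequenceRecord("g1", random_dna(rng, 2000) + elem.sequence + random_dna(rng, 2000))
    m = presence_absence([elem], [genome])
    assert m.is_present("g1", "el")
    ident, cov = m.cells[("g1", "el")]
    assert ident == pytest.approx(1.0) and cov == pytest.approx(1.0, abs=0.01)


def test_half_length_fragment_is_absent(rng):
    elem = SequenceRecord("el", random_dna(rng, 1000))
    frag = mutate_to_identity(elem.sequence[:500], 0.95, 1)
    genome = SequenceRecord("g1", random_dna(rng, 1500) + frag + random_dna(rng, 1500))
    m = presence_absence([elem], [genome])
    assert not m.is_present("g1", "el")


def test_matrix_matches_brute_force_plan(rng):
    """6-genome panel with planted homologs equals the intended design."""
    elem = SequenceRecord("el", random_dna(rng, 800))
    plan = {  # genome -> (identity, covered fraction)
        "g1": (1.00, 1.0), "g2": (0.90, 1.0), "g3": (0.85, 0.8),
        "g4": (0.70, 1.0), "g5": (0.95, 0.4), "g6": None,
    }
    genomes = []
    for name, design in plan.items():
        if design is None:
            seq = random_dna(rng, 3000)
        else:
            ident, frac = design
            piece = mutate_to_identity(elem.sequence[: int(800 * frac)], ident, 3)
            seq = random_dna(rng, 1000) + piece + random_dna(rng, 1000)
        genomes.append(SequenceRecord(name, seq))
    m = presence_absence([elem], genomes, HomologyCriteria(0.80, 0.60))
    expect = {name for name, design in plan.items()
              if design and design[0] >= 0.80 and design[1] >= 0.60}
    assert set(m.present_species("el")) == expect


# ---------------------------------------------------------------- PI test

def test_textbook_incongruence_is_true():
    ok, rep = pi_test("((A,B),C);", "((A,C),B);", "A", "B")
    assert ok
    assert rep["sisters_in_candidate"] and not rep["sisters_in_species"]


def test_congruent_topologies_fail():
    ok, _ = pi_test("((A,B),C);", "((A,B),C);", "A", "B")
    assert not ok


def test_multifurcating_candidate_clade_fails():
    ok, rep = pi_test("(A,B,C);", "((A,C),B);", "A", "B")
    assert not ok
    assert set(rep["candidate_clade"]) == {"A", "B", "C"}


def test_missing_species_names_offending_tree():
    with pytest.raises(ValueError, match="candidate"):
        pi_test("((A,D),C);", "((A,B),C);", "A", "B")


def test_pi_invariant_under_child_order():
    for cand in ("((A,B),C);", "((B,A),C);", "(C,(A,B));"):
        ok, _ = pi_test(cand, "((A,C),B);", "A", "B")
        assert ok


# ---------------------------------------------------------------- PD test

def _matrix(species, present, element="el"):
    from interchange.screen import PresenceAbsenceMatrix
    cells = {(s, element): (0.95, 0.9) for s in present}
    return PresenceAbsenceMatrix(species, [element], cells)


TREE10 = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):2):1,(I:1,J:4):1);"


def test_element_only_in_partners_is_patchy():
    m = _matrix(list("ABCDEFGHIJ"), ["A", "E"])
    ok, rep = pd_test(m, TREE10, "A", "E")
    assert ok and rep["mode"] == "only_partners"


def test_element_everywhere_is_not_patchy():
    m = _matrix(list("ABCDEFGHIJ"), list("ABCDEFGHIJ"))
    ok, _ = pd_test(m, TREE10, "A", "E")
    assert not ok


def test_close_relative_lacking_element_is_patchy():
    # A and E partners; element in E's whole neighborhood but absent in B,
    # A's sister -> patchy
    m = _matrix(list("ABCDEFGHIJ"), ["A", "E", "F", "G", "H", "I", "J", "C", "D"])
    ok, rep = pd_test(m, TREE10, "A", "E")
    assert ok
    assert "B" in rep["missing_close_relatives"]


def test_pd_uses_topology_when_no_branch_lengths():
    tree = "(((A,B),(C,D)),(E,F));"
    m = _matrix(list("ABCDEF"), ["A", "E", "F", "C", "D"])
    ok, rep = pd_test(m, tree, "A", "E")
    assert ok and "B" in rep["missing_close_relatives"]


# ---------------------------------------------------------------- neighbor joining

def _topology(newick: str, taxa):
    tns = dendropy.TaxonNamespace(list(taxa))
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    t.encode_bipartitions()
    return {b.split_as_bitstring() for b in t.bipartition_encoding if not b.is_trivial()}


def test_additive_matrix_recovers_known_topology():
    # tree ((A:1,B:2):1,(C:3,D:4)); pairwise path lengths
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], float)
    nwk = nj_tree(d, ["A", "B", "C", "D"])
    assert _topology(nwk, "ABCD") == _topology("((A,B),(C,D));", "ABCD")


def test_three_taxa_unique_topology():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    nwk = nj_tree(d, ["A", "B", "C"])
    assert nwk.count(",") == 2


def test_nj_invariant_under_taxon_permutation():
    rng = np.random.default_rng(3)
    n = 6
    # random additive-ish matrix from random positive branch tree distances
    pts = rng.uniform(0, 10, (n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    taxa = ["A", "B", "C", "D", "E", "F"]
    base = _topology(nj_tree(d, taxa), taxa)
    perm = [3, 1, 5, 0, 2, 4]
    d2 = d[np.ix_(perm, perm)]
    taxa2 = [taxa[i] for i in perm]
    assert _topology(nj_tree(d2, taxa2), taxa) == base


def test_asymmetric_matrix_rejected():
    with pytest.raises(ValueError):
        nj_tree([[0, 1, 2], [9, 0, 1], [2, 1, 0]], ["A", "B", "C"])


def test_nj_topology_agrees_with_ape(tmp_path):
    """Independent oracle: ape::nj on the same distance matrix."""
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 5, (7, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    taxa = list("ABCDEFG")
    mine = nj_tree(d, taxa)
    csv = tmp_path / "d.csv"
    np.savetxt(csv, d, delimiter=",")
    script = tmp_path / "nj.R"
    script.write_text(
        f'd <- as.matrix(read.csv("{csv}", header=FALSE));'
        f'rownames(d) <- colnames(d) <- c({",".join(repr(t) for t in taxa)});'
        'library(ape); t <- nj(as.dist(d));'
        f'write.tree(t, "{tmp_path}/ape.nwk")'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ape_nwk = (tmp_path / "ape.nwk").read_text()
    assert _topology(mine, taxa) == _topology(ape_nwk, taxa)


# ---------------------------------------------------------------- copy number

def _copy_number_fixture(c, seed):
    rng = np.random.default_rng(seed)
    # an aged TE: its two LTRs have diverged, so reads place uniquely
    elem = mutate_to_identity(_random_te(rng, 5000), 0.95, seed + 7)
    genes = [_random_gene(rng, 1200) for _ in range(8)]
    parts = [random_dna(rng, 1500)]
    for _ in range(c):
        parts += [elem, random_dna(rng, 1500)]
    for g in genes:
        parts += [g, random_dna(rng, 1500)]
    genome = "".join(parts)
    r1, r2 = simulate_reads(genome, coverage=20, base_error_rate=0.02,
                            seed=seed + 1, species="x")
    return (SequenceRecord("elem", elem), r1 + r2,
            [SequenceRecord(f"g{j}", g) for j, g in enumerate(genes)])


def test_single_copy_estimate_near_one():
    elem, reads, genes = _copy_number_fixture(1, 210)
    est = copy_number(elem, reads, genes)
    assert 0.8 <= est.copy_number <= 1.2


def test_three_copy_estimate_near_three():
    elem, reads, genes = _copy_number_fixture(3, 230)
    est = copy_number(elem, reads, genes)
    assert 2.5 <= est.copy_number <= 3.5


def test_copy_number_requires_gene_depth(rng):
    elem = SequenceRecord("el", random_dna(rng, 500))
    genes = [SequenceRecord("g", random_dna(rng, 500))]
    reads = [SequenceRecord("r", elem.sequence[:150])]
    with pytest.raises(ValueError):
        copy_number(elem, reads, genes)


# ---------------------------------------------------------------- transfer age

def test_age_identity_one_is_zero():
    assert age_estimate(1.0).mya == 0.0


def test_age_97_percent_is_1_15_mya():
    assert age_estimate(0.97, 1.3e-8).mya == 1.15


def test_age_89_percent_closed_form():
    assert age_estimate(0.89, 1.3e-8).mya == 4.23


def test_age_monotone_and_rate_scaling(rng):
    ids = np.sort(rng.uniform(0.5, 1.0, 50))
    ages = [age_estimate(float(p)).years for p in ids]
    assert all(a >= b for a, b in zip(ages, ages[1:]))
    assert age_estimate(0.9, 2.6e-8).years == pytest.approx(
        age_estimate(0.9, 1.3e-8).years / 2
    )
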