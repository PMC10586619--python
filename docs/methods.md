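# Methods

This note documents the models and procedures implemented in
`interchange`, the parameter choices that matter, what the synthetic
benchmark does and does not emulate, and the package's known limitations.

## Read-level homology screen

Both species' reads are decomposed into canonical k-mers (k = 30 by
default; the lexicographic minimum of a window and its reverse complement,
so reverse-strand homology is found; windows containing N are skipped).
The similarity of a read is the length of the union of its k-windows whose
canonical form occurs in the other species' index, divided by the read
length. Reads at or above the threshold (default 0.5) are retained; when
reads are paired, the mate of a retained read is retained too, which
preserves pairing through assembly and bridges short gaps between retained
blocks.

Two scoring modes are provided (`retention_mode`):

* `per_read` (default): a read is scored against the whole k-mer index of
  the other species, the natural reading of a k-mer search that reports
  query positions without subject identities.
* `per_pair`: every cross-species read pair sharing k-mers is scored on
  both sides and retained only if min(S_a, S_b) ≥ threshold. This is
  stricter — a read's score is capped by a single partner's reading
  frame — and is provided for comparison; the two modes give near-identical
  retained sets on deeply covered data.

The screen is exact (no sketching). k-mers are packed 2 bits/base into
`uint64` arrays; matching is sorted-array intersection and scoring is a
grouped interval-union reduction, so hundreds of thousands of reads are
processed in seconds on one core.

**Sensitivity model.** A read is retained only if ≥ 50% of its length lies
in exact-match runs of ≥ k bases. For a locus at identity p with randomly
placed substitutions, the expected fraction of positions inside such runs
is e^(−k(1−p))(1 + k(1−p)): ≈ 0.77 at p = 0.97, 0.46 at p = 0.94, 0.31 at
p = 0.92. Detection of whole elements therefore falls off sharply below
about 93–94% identity under the default parameters — an intrinsic property
of the k = 30 / 50% rule on 150 bp reads, which the end-to-end benchmark
(below) quantifies rather than hides.

## Low-complexity filter

Simple repeats share k-mers between unrelated genomes, so retained reads
are filtered with a whole-read dust score over overlapping triplets:
`dust = 100 · Σ_t c_t(c_t−1)/2 / S_max` with `S_max = (W−2)(W−3)/2`. The
normalization makes a homopolymer score exactly 100 and a read with all
triplets distinct exactly 0; triplets containing N are excluded and W
reduced accordingly. Reads with dust > 10 are removed (a read exactly at
the threshold is kept). Whole-read scoring was chosen over sliding windows
because it is self-consistent at both extremes; fidelity to any particular
external tool's windowing is not claimed.

## Assembly

Retained reads of each species are assembled separately with a minimal de
Bruijn assembler: canonical k-mers (default k_asm = 55, odd), dangling tip
unitigs shorter than 2·k_asm removed, bubble branches below 10% of their
sibling's depth removed, maximal unbranched paths emitted as scaffolds in
canonical orientation, sorted by length (ties by sequence, so output is
deterministic). It is designed for the screen's output — short,
high-identity, low-error read subsets — not whole genomes; the pipeline
accepts externally assembled scaffolds in place of the built-in assembler
for real data. Mate-pair gap scaffolding (joining contigs across
uncovered gaps with Ns) is deliberately not implemented; consequently a
locus whose retained-read coverage is interrupted by > ~700 bp assembles
into several scaffolds rather than one.

## Annotation

Scaffolds are aligned to FASTA databases whose headers carry
`db:{gene|TE|MCR}` and optional `superfamily:`/`lineage:` tokens.
Nucleotide mode seeds with exact 11-mers, clusters seeds by diagonal, and
extends with a banded edit-distance alignment re-scored as match +1,
mismatch −2, gap open −5, gap extend −2. Translated mode translates the
query in six frames (internal stops retained — TE ORFs are often
fragmented), seeds with amino-acid 4-mers and extends with BLOSUM62
(−11/−1) local alignment. No e-values are computed; hits are filtered by
identity (0.70 nucleotide / 0.30 translated) and query coverage (0.30)
floors instead — Karlin–Altschul calibration is out of proportion for the
database sizes involved, and the floors are config-exposed. A scaffold
takes the category of its best-scoring hit (ties: higher identity, then
MCR > TE > gene, so organellar exclusion stays conservative); scaffolds
classified MCR never become candidates. TE lineage frequencies count each
read once toward its best-scoring protein and report counts relative to
total aligned reads.

## Candidate calling

The high-similarity threshold is computed from the percent identities of
globally aligned orthologous gene pairs: **HS = Q3 + IQR/2**, quartiles by
linear interpolation at rank (n−1)q (the most common convention; at least
4 orthologs are required). Scaffolds are paired across species by
reciprocal best hit on the local-alignment score; ties for a best hit mean
paralog ambiguity and drop the pair. A pair becomes a candidate when its
alignment identity ≥ HS (boundary inclusive), both scaffolds are
≥ 1 kb, and it is not MCR. The 1 kb floor applies to the shorter scaffold
of the pair. Candidates are clustered by single linkage (scaffolds
aligning at ≥ 80% identity over ≥ 80% of the shorter sequence) to collapse
paralogous copies.

## Post-screens

* **PI** — true iff the smallest clade containing the two partners in the
  element tree contains no other taxon (a multifurcation containing extras
  fails) while in the species tree it does. Trees are consumed as Newick;
  a deterministic neighbor-joining builder (ties broken by taxon label
  order) is included for when no externally built tree is available.
* **PD** — true iff the element is present only in the two partners, or
  some panel species closer to either partner than the partners are to
  each other lacks it. "Closer" uses patristic distance when branch
  lengths exist, edge counts otherwise; presence requires hits at ≥ 80%
  identity covering ≥ 60% of the element (merged intervals).

## Copy number and age

Reads are placed best-hit-only (lowest edit distance, ≥ 95% identity)
on the element and on single-copy genes; multi-mapping reads count once.
`copy number = MCT / MCB` where MCT is the median per-base depth over the
element and MCB the median across genes of each gene's median depth.
Because placement is unique-best, an element containing a long internal
exact repeat (e.g. a *young* LTR-retrotransposon with identical terminal
repeats) piles the repeat's reads onto one copy of the repeat and
underestimates depth elsewhere; elements whose repeats have diverged a few
percent (any transfer older than ~1 My) are unaffected.

Transfer age uses the raw p-distance and the Ma & Bennetzen rate:
T = (1 − p) / (2r), r = 1.3 × 10⁻⁸ substitutions/site/year, reported in
Mya to 2 decimals. No multiple-hit correction is applied: with it, 97%
identity maps exactly to 1.15 Mya. Note the closed form gives 4.23 Mya at
89% identity; a published range endpoint of 3.8 Mya for that identity is
not reproducible from this formula and would require either a different
identity or a substitution-model correction — the package implements the
stated closed form and leaves the discrepancy documented here.

## Synthetic benchmark

`generate_genome_pair` builds an ancestral sequence of uniform base
composition, plants non-overlapping ORF-bearing genes (1–3 kb: start
codon, stop-free codons, terminal stop) and LTR-structured TEs (2–8 kb
with identical terminal repeats, superfamily/lineage labels cycling
through a configurable mix), and derives two descendants by substituting
disjoint position sets at rate divergence/2 each — so the realized
pairwise identity is exactly 1 − divergence and coordinates lift over
unchanged. `insert_transfers` copies sampled donor features into the
recipient at a target identity drawn uniformly from a range (default
0.80–1.00, substitution-only; exactly round((1−p)·L) positions change), at
uniform positions outside existing features, recording every event in a
truth table. `simulate_reads` emulates a wgsim-style run: uniform
fragments, insert length ~ Normal(350, 35) truncated at twice the read
length, 150 bp mates (second mate reverse-complemented), uniform
substitution errors (default 2%), constant Q30 qualities, read count =
coverage · L / (2 · 150). The 350 bp fragment size, 150 bp reads and 20X
coverage mirror the sequencing protocol the pipeline targets; the insert
SD and Q30 are this package's choices.

Evaluation: a truth event is *recovered* when the candidate scaffolds'
≥ 80%-identity alignments collectively cover ≥ 50% of the inserted copy; a
candidate is a *false positive* when none of its alignments to any
inserted copy covers ≥ 50% of the copy or of the candidate's own scaffold
(a fragment of a genuinely transferred element is a partial detection, not
a spurious locus — counting it as a false positive would turn one miss
into two errors). The TP/FP curve sweeps the minimum-scaffold-length
filter over {0, 500, 1000, 1500, 2000} bp.

What the benchmark does *not* emulate: real TE paralog families (each
simulated element is single-copy in its genome, so no family member can
rescue a missed locus), indels (mutations are substitution-only),
GC/repeat composition biases, and coverage nonuniformity beyond Poisson
sampling. Passing it therefore demonstrates the pipeline's mechanics and
its intrinsic identity-dependent sensitivity, not performance on real
genomes.

**Benchmark scale and measured behavior.** The standard fixture uses two
2 Mb genomes at 0.35 divergence carrying 120 genes + 120 TEs each, with
20 gene + 20 TE transfers of ≥ 1.5 kb at 90–100% identity and error-free
20X reads; the ortholog baseline uses 50 gene pairs (HS lands near 69%
identity). On one CPU the full run takes ~5 minutes. Transfers above ~94%
identity are recovered essentially always, transfers below ~92% rarely
(see the sensitivity model above); recall over the 90–100% range is
therefore ~0.5–0.7 depending on the draw, with 0–2 false positives, and
the zero-transfer control yields no candidates. The published pipeline
mitigates the low-identity falloff with paired-end gap scaffolding in its
external assembler, which is outside this package's assembly scope.

## Numerical and determinism notes

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give bitwise
  identical outputs, including assembly (lexicographic traversal order)
  and NJ (label-order tie-breaks).
* Quantiles: linear interpolation at rank (n−1)q; boundary comparisons
  (similarity threshold, dust threshold, HS, 1 kb filter) are inclusive
  on the retained side.
* Gap cost convention: a length-L gap costs 5 + 2(L−1) (nucleotide) —
  the open penalty covers the first gap base.
* Degenerate inputs: empty read sets assemble to nothing; an empty
  candidate list writes a header-only report; fewer than 4 orthologs is an
  error instructing a manual HS; zero gene depth makes the copy-number
  estimate an explicit error rather than infinity.
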