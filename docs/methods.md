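# Methods

This note records the models, conventions, and design choices behind
`mitoscan`, in the order the pipeline applies them.

## Sequence model and coordinates

All sequences are held internally in the RNA alphabet; DNA input is
accepted and `T` is normalized to `U` on ingestion (public-database
deposits are DNA-alphabet, while codon logic is stated in RNA form).
IUPAC ambiguity letters are retained — transcriptome contigs contain `N`
runs at coverage gaps — and are handled downstream as untranslatable: a
codon containing any non-ACGU letter translates to `X` and never matches
a start or stop codon. Coordinates are 0-based and half-open everywhere.

## ORF annotation

Genetic-code tables come from the NCBI tables via Biopython; code 4
differs from the standard code exactly at UGA (Trp vs stop), which is
asserted as an invariant. Only the three plus-strand frames are scanned
by default, because mitovirus genomes are plus-strand RNAs with the RdRp
ORF on the plus strand. Within a frame, segments are bounded by in-frame
stops and sequence ends; each segment's candidate ORF runs from the
segment's first AUG through the closing stop (inclusive) or, if
unterminated, through the last complete codon. The candidate maximizing
`end − start` is primary; because the terminal stop is included in the
span, a stop-terminated ORF beats an unterminated one of equal coding
length. Ties break toward smaller start, then smaller frame.

Completeness is classified from stop-codon evidence alone: a terminal
stop makes the coding region complete at the 3′ side; an additional
in-frame stop upstream of the start codon (found in the 5′ NTR) shows
that no N-terminally longer product can be encoded, giving the strongest
call. Contigs whose reading frame runs off the 5′ end before any stop
get the weaker call; unterminated ORFs are flagged 3′-incomplete.

### Alternative start codons

The first-in-frame-AUG convention can misplace the start. Two refinements
are provided. `extend_with_alternative_start` enumerates in-frame AUG,
GUG, or AUU codons strictly between the nearest upstream in-frame stop
and the current start; each is a candidate N-terminal extension. The
initiator residue is reported as the plain table amino acid (V for GUG,
I for AUU) — whether the initiator is read as fMet is left to the
translation system and flagged in the docstring rather than decided.

`propose_start_by_conservation` scores candidates across a strain
collection: every taxon's candidate proteins (baseline, upstream
extensions, and downstream in-frame AUGs up to the third) are globally
aligned to the longest taxon, and a candidate scores the number of
reference columns within an N-terminal window (default 30 columns) whose
residue is shared by at least `min_support` taxa (default 2). Ties break
toward the candidate with fewer leading unshared residues, which is what
lets a downstream AUG win when a taxon's first AUG adds residues nobody
else shares. The window and support threshold are configurable because
the underlying conservation argument is qualitative; this scoring rule is
one concrete formalization of it, not a community standard.

## Codon usage

`codon_usage` counts codons over the coding region only; the terminal
stop is excluded by contract (callers pass the coding region), and
ambiguous codons are excluded from counts but tallied separately so that
`counts + ambiguous = length / 3` always holds. The headline statistic is
the Trp UGA fraction `n(UGA) / (n(UGA) + n(UGG))`, undefined (None) for
Trp-free regions. Pooling across genes sums counts and then recomputes
the fraction — a mean of per-gene fractions would weight short genes up.
Fractions are reported raw and as integer-rounded percentages.

## Pairwise alignment and identity

The aligner is an affine-gap Needleman–Wunsch (three-state DP, numba-
jitted) with EMBOSS-default scores: nucleotide match +5 / mismatch −4
(ambiguity letters match only themselves), BLOSUM62 for proteins, gap
open 10, extend 0.5. A gap run of length L costs `open + (L−1)·extend`.
By default terminal gap runs are free: a gap run in one sequence lying
before the first or after the last residue of the other costs nothing
(the per-sequence end-gap definition, so a double overhang at a corner is
handled correctly). Percent identity divides identical columns by total
alignment columns, gap columns included; a flag offers the
shorter-sequence denominator. When co-optimal alignments exist the
traceback deterministically prefers diagonal over up over left; identity
is reported for that single traceback.

Two consumers deliberately penalize end gaps instead:

* `protein_p_distance` excludes gap columns from both numerator and
  denominator, so free terminal gaps would silently drop terminal
  residues from the comparison; penalizing end gaps forces them to pair.
* `check_cds_indel_free` receives complete annotated coding regions, so
  a terminal overhang is a real indel; with free ends, terminal
  substitutions would be converted into spurious staggered gap columns.

## Species delimitation

Clustering is single linkage: connected components of the graph with an
edge wherever identity strictly exceeds `tau_within` (default 86 %).
Threshold comparisons are strict on both sides (> 86 %, < 50 %), matching
the demarcation phrasing. With the wide within/between gap the data show,
the linkage choice is immaterial; single linkage makes the borderline
behavior explicit and testable. `check_partition_gap` verifies the gap:
`min_within` over intra-cluster pairs of non-singleton clusters (None,
vacuously satisfied, when all clusters are singletons) and `max_between`
over inter-cluster pairs, with the worst offending pair reported.

Consensus trimming anchors every strain to the longest strain of its
cluster as coordinate reference (the longest reference minimizes lost
columns). At each terminus the outermost reference column at which at
least two strains carry an identical residue defines the trim boundary;
residues outside the boundaries, including insertions relative to the
reference, are removed from every strain. The operation is idempotent.
Single-strain clusters cannot be trimmed and are passed through
unchanged by the pipeline.

## Phylogeny

The within-collection tree is a desk-scale, dependency-light alternative
to maximum-likelihood inference, sufficient to display the
clade-per-species structure: protein p-distances feed classical neighbor
joining (Saitou–Nei Q criterion, standard branch-length formulas, final
three-point trifurcation). Negative branch-length estimates are clamped
to 0 with the deficit logged. Trees are `skbio.TreeNode` objects;
midpoint rooting is implemented in-repo (ties between equally long
leaf-to-leaf paths break toward the lexicographically smallest leaf
pair, and a midpoint falling exactly on a node roots at that node).
Newick round-trips through scikit-bio's parser. Bootstrap support has no
analog here and is not reported.

## Synthetic data

The generator emulates the genome architecture of the study system so
that every stage has tracked ground truth:

| parameter | default | unit |
|---|---|---|
| species × strains | 8 × 4 | — |
| RdRp length | uniform 636–757 | aa |
| 5′ NTR | uniform 105–477 | nt |
| 3′ NTR | uniform 1–175 | nt |
| Trp codons per genome | uniform 10–17 | count |
| Trp UGA fraction | uniform 0.38–0.77 | — |
| pairwise strain identity | uniform 0.87–0.99 | — |
| NTR indels between strains | on, 5′-biased | — |

Each species ancestor gets a uniform-background CDS with the drawn Trp
composition placed at random positions, a terminal stop, a 5′ NTR with an
in-frame stop near the CDS (in-frame AUGs between that stop and the
start are scrubbed, since they would move the annotated start), and a
random 3′ NTR. Every emitted genome is re-annotated at generation time
and must reproduce its own truth record exactly, so the generator cannot
emit inconsistent fixtures; rare architectural accidents are rejection-
sampled away.

Strains derive from the ancestor by coding-region substitutions only.
The substitution count is solved analytically from the identity target:
each strain receives `round((1−t)/2 · n)` substitutions at positions
disjoint across strains, so the pairwise identity of two strains is
`1 − (k_i + k_j)/n` and lands within two percentage points of the mean
of their targets even with NTR indels. Positions are third codon
positions (divergence under purifying selection is overwhelmingly
synonymous), which also keeps mismatches isolated so that optimal
alignment of strain coding regions stays gap-free; substitutions never
create stops and never touch Trp codons — the number, UGA/UGG split, and
positions of Trp codons are conserved among strains, as observed across
real isolates. Optional small NTR indels (5′-biased) stay strictly
upstream of the designed stop or downstream of the ORF, leaving the
coding architecture untouched. Distinct species are independent draws;
their pairwise identity is not enforced but empirically lands near 45 %,
below the 50 % demarcation line.

What the generator does **not** emulate: sequencing reads, coverage
profiles and assembly errors (beyond injectable N-gaps, truncations and
premature stops), base-composition and codon-usage biases of real
mitochondrial systems, recombination, and within-strain polymorphism.
Passing tests therefore demonstrate the pipeline's correctness on
genomes with the stated architecture, not robustness to assembly
artifacts or to identity distributions that straddle the thresholds.

A second generator emits a 12-gene mitochondrial core-gene transcript
set (atp6…nad6, realistic product lengths) in two presets: a UGA-rich
system with pooled Trp-UGA usage 21/60 = 35 % and a UGA-poor comparator
with 6/68 = 8.8 %, with atp6/atp9/nad3 carrying at most a single UGG and
never UGA. The cox1 transcript is built with its true start at an
upstream in-frame GUG: the first-AUG product is 33 aa shorter than the
528-aa (1587-nt) GUG-extended product, exercising the alternative-start
machinery on a known case.

Degradations (`inject_degradations`) model the observed data artifacts:
N-run coverage gaps, terminal truncations (which can delete the upstream
stop and weaken the completeness call), and a premature stop substituted
k codons before the natural end, shortening the annotated protein by
exactly k residues.

## Numerical and scale choices

* DP matrices are float32; scores are integer/half-integer multiples far
  below the float32 exactness limit, so score comparisons are exact.
* Negative NJ branch lengths clamp to 0 (standard practice; keeps the
  tree invariant testable); the clamp deficit is logged.
* The acceptance script uses 20 generator seeds for the truth-recovery
  rate and one full-scale dataset (32 genomes, 496 alignments) for the
  delimitation quantities; the test suite covers 100 seeds for
  annotation recovery and uses reduced-scale collections (4 species × 3
  strains, 150–200 aa) where the full genome length adds nothing to the
  property under test.
* Known limitation: on rare seeds a local sequence repeat makes a
  compensating 1-nt gap pair score-optimal in one within-species CDS
  alignment, so the indel-free fraction reported by the acceptance
  script can dip below 1.0. This is a property of optimal affine-gap
  alignment at EMBOSS-default costs, not of the annotation; the gap
  columns come in compensating pairs and leave lengths conserved.
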