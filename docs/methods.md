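# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Family identification

Membership is a two-gate decision. The screening gate aligns every
proteome entry locally against each seed query (Smith–Waterman with
affine gaps; a gap of length L costs `gap_open + L*gap_extend`, the
BLAST convention). Defaults are BLOSUM62, gap open 11, gap extend 1,
minimum identity 30% over aligned columns and minimum query coverage
0.5. These are conventional homology-search settings, not measured
constants; they are configurable and recorded in the run manifest. A
subject passes if *any* query clears both thresholds, and keeps its
best-scoring qualifying alignment as evidence. Pairwise alignment is
computed by Biopython's `PairwiseAligner` (an exact Gotoh
implementation); the test suite independently verifies its scores
against an exhaustive dynamic program that enumerates every gap length
explicitly.

The confirmation gate requires the three diagnostic NBD motifs in N→C
order: Walker A `[AG]x(4)GK[ST]` (exact), the ABC signature `LSGGQ`
with at most one mismatch, and Walker B — four residues from
{I,L,V,F,M,A} followed by `DE` (exact). The one-mismatch signature
budget reflects the well-known degeneracy of the signature while the
Walker patterns are kept exact; the search reports the leftmost ordered
chain, falling back to independent leftmost occurrences (unconfirmed)
for diagnosis. This ordered-consensus check replaces a profile-HMM
domain model; it captures the same three elements a Pfam ABC-transporter
domain hit is built on, at the cost of ignoring position-specific
weights. A user-supplied PSSM can be layered on top, but no HMM is
implemented.

Members are named `prefix+1 … prefix+n` along chromosomes, with natural
ordering of chromosome identifiers (`chr2` before `chr10`) and ascending
start; naming is independent of input order.

## Protein characterization

Average (not monoisotopic) residue masses are used, matching standard
protein-parameter tools. pI solves net-charge(pH) = 0 by bisection on
[0, 14]; the charge model is Henderson–Hasselbalch over the Bjellqvist
pKa set (N-terminus 7.5 with residue-specific corrections for
A/M/S/P/T/V/E, C-terminus 3.55 corrected for terminal D/E, side chains
C 9.0, D 4.05, E 4.45, H 5.98, K 10.0, R 12.0, Y 10.0). Bisection runs
until the pH bracket is below 1e-6 *and* |charge| < 1e-4 — the charge
criterion alone leaves too much pH slack where the titration curve is
flat. The charge function is strictly decreasing in pH so the zero is
unique; tests verify agreement with a fine-grid charge-zero scan to
1e-3 and with Biopython's ProtParam (whose own bisection is bracketed to
[4.05, 12] and saturates outside it).

The instability index uses the Guruprasad dipeptide weights with 10/L
normalization; the stability call uses the published threshold with
strict inequality (an index of exactly 40 is stable). The aliphatic
index is `X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)` in mole percent.
GRAVY is the mean Kyte–Doolittle value; exactly 0 classifies as
hydrophobic (hydrophilic requires strictly negative). The pI class
bands default to acidic < 6.5 ≤ neutral ≤ 7.5 < basic — a symmetric band
around neutrality chosen as package policy, since no canonical band
exists; both bounds are configurable.

Transmembrane segments come from a deliberately transparent
hydropathy-window caller: every 19-residue window with mean
Kyte–Doolittle hydropathy ≥ 1.6 is a candidate, and overlapping windows
merge into maximal segments. This is a stand-in for HMM-based TM
prediction, flagged as such (`tm_caller: kyte-doolittle-window`) in every
report: it finds strongly hydrophobic helices but has neither topology
nor signal-peptide awareness, so TM counts are indicative, not
reproductions of an HMM predictor's output.

## Phylogeny

The progressive aligner builds a guide tree by neighbor-joining on
k-mer distances (k = 3, distance `1 − shared/min`), then merges profiles
bottom-up with global affine-gap (Gotoh) profile alignment; column
scores are frequency-weighted BLOSUM62 dot products with gaps
contributing zero. It exists to keep the pipeline free of external
binaries and is adequate at the tens-of-sequences scale this package
targets; it makes no claim of matching a production MSA program's
accuracy on hard alignment problems.

Distances are p-distance by default (Poisson correction
`−ln(1 − p)` by flag); sites with a gap in either row are excluded
pairwise, and a pair with no shared ungapped site is an error, not a
silent zero. Neighbor-joining follows the Saitou–Nei Q-criterion;
Q-matrix ties break toward the lowest (row, column) pair in current node
order and negative branch lengths are clamped to zero, making trees
reproducible bit for bit and label-order independent up to isomorphism.
On additive matrices the algorithm recovers the generating topology and
branch lengths exactly — the module's core test oracle, cross-checked
against scikit-bio's independent NJ implementation.

Bootstrap resamples alignment columns with replacement; support is the
percentage of replicate trees containing each internal bipartition of
the full-data tree. Rows are processed in sorted label order so supports
are invariant to input leaf order under a fixed seed. The default of
1000 replicates follows the common convention for family surveys. A
replicate whose resampled columns leave a distance undefined is redrawn
within a bounded budget.

Subfamily assignment is nearest-reference by tree path length: each
unlabeled leaf takes the subfamily of its closest reference leaf (ties
break toward the larger reference set, then lexicographically). In the
pipeline the seed queries double as reference leaves.

## Duplication classification

Tandem: two members on the same chromosome with at most one intervening
gene — counted over *all* annotated genes, the stricter reading of
"intervening" — and global-alignment identity ≥ 70%. The identity
threshold operationalizes "homologous" for the adjacency rule; it is
deliberately permissive (tandem-duplicated genes retain similar lengths
and structures) and configurable. Segmental: any non-tandem member pair
with identity strictly above 80% (a pair at exactly 80.0% is excluded)
and coverage ≥ 0.5 of both sequences in residue-paired columns. Identity
is computed over residue-paired columns of a global alignment; the
mutual-coverage floor excludes short domain-only matches from being
called duplications. Tandem and segmental sets are disjoint by
construction, and pairs are reported canonically (lexicographic gene
order), so results are order-independent.

## Motifs, promoters and allele comparison

Protein motifs are consensus strings over the 20 amino acids plus
B={N,D}, Z={Q,E}, J={I,L} and X=any. A window matches when its mismatch
count is at most `floor(width × 0.1)`; hits per motif are
non-overlapping and leftmost-greedy (like discovered motif site lists),
reported in N→C order. Motif widths are always recomputed from the
consensus, and the printed E-values of the packaged table are carried as
opaque text — values like `4.9 x 10^-1822` underflow doubles and are
metadata only.

The promoter is the 2 kb upstream of the *translation* start (first CDS
base on the coding strand), not the transcription start: plus-strand
genes take `[cds_start−2000, cds_start−1]` read forward, minus-strand
genes take `[cds_end+1, cds_end+2000]` reverse-complemented; truncation
at a contig edge is flagged. Cis-elements are IUPAC patterns scanned on
the sense strand only (a both-strands flag exists but is off by
default), with every overlapping occurrence counted — database-scanner
behavior, intentionally asymmetric to the non-overlapping motif policy.

Allele comparison globally aligns two promoter sequences (nucleotide
scores +2/−3, gap open 10, extend 0.5), reports contiguous gap runs as
deletion segments (sequence, length, 1-based offset in the allele
retaining the bases), and diffs the element scans of the two alleles
into lost/gained counts; swapping alleles swaps lost and gained.
Comparisons below 50% alignment identity are refused with diagnostics
rather than reported.

## Expression

Relative expression is the standard 2^−ΔΔCt statistic with an internal
reference gene; replicate Ct values are averaged before the ΔΔCt
arithmetic. Fold-change matrices are log2-transformed with a
configurable pseudocount (default 0, appropriate for qPCR-derived
relative values). A gene×treatment profile is called induced when any
timepoint reaches the fold threshold (default 2, inclusive); "strongly
induced" has no canonical numeric definition, so the threshold is
labeled as package policy in reports and is configurable. Microarray
preprocessing is out of scope — the module consumes already-summarized
tables.

## Synthetic data

The generator emulates the setting of a genome-wide family survey at
desk scale. Defaults: 4 chromosomes of 120 kb; 16 family genes and 14
decoys; 2 tandem clusters (members at 92% protein identity, one
intervening decoy); 2 cross-chromosome segmental pairs at 88% identity
(comfortably above the 80% classification boundary after the ±0.5
substitution rounding); 1 cross-chromosome distractor pair at 75%
identity that must *not* be called segmental; intronless fraction 0.25;
5–8 cis-elements planted per family promoter. Family proteins derive
from two template proteins (defining two subfamilies) mutated to 62%
identity with the three NBD motif segments protected; decoys are random
proteins scrubbed of all three motifs. These sizes keep every
all-against-all step interactive while exercising each classification
boundary from both sides.

Mutations are substitutions only, so identity is exact position-wise
accounting; reverse translation samples synonymous codons uniformly and
introns (GT…AG, 64–263 bp) are inserted only between complete codons, so
conceptual translation of every spliced CDS reproduces the protein
exactly. Genes are laid out with 4.5 kb clearance so promoter windows
never overlap neighboring genes; planted elements go to recorded,
non-overlapping sense-strand offsets (with 3 bp clearance), and every
unplanted dictionary occurrence in a family promoter is mutated away, so
planted counts are exactly recoverable. All randomness flows from one
seeded generator: identical configuration and seed give byte-identical
FASTA/GFF3/TSV output.

What the generator does **not** emulate: indels and rearrangements,
codon usage bias, GC structure, pseudogenes, alternative transcripts,
overlapping genes, whole-genome duplication history, or realistic
promoter composition. Passing the planted-truth tests therefore shows
that the pipeline's rules and thresholds are implemented correctly and
are mutually consistent — not that the thresholds are optimal for real
genomes, where fragmented assemblies, partial gene models and
evolutionary noise dominate.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive everywhere (GFF3 convention);
half-open arithmetic never leaves module internals. Readers reject
rather than repair malformed input (duplicate FASTA ids, orphan GFF3
features, CDS outside exons, inconsistent declared motif widths).
Single-sequence alignment inputs return degenerate one-row alignments;
motifs wider than the protein yield no hits; short sequences yield no TM
windows; an empty proteome screens to an empty result. Scores and
distances are floats compared with explicit tolerances in tests (1e-9
for additive-tree recovery, 1e-3 for pI).

## Problem sizes

The bundled test fixture and the acceptance run use the generator
defaults above (30 genes across 4×120 kb chromosomes, ~380-residue
proteins), 200–1000 bootstrap replicates, oracle suites of 100–200
random instances, and brute-force alignment oracles on 8–30-residue
sequences — sizes chosen so the full suite exercises every code path in
well under a minute per module.

## Known limitations

* The screening thresholds, tandem-homology identity, and pI class bands
  are explicit package policy where the field has no single convention;
  survey counts on real genomes are sensitive to them.
* The TM caller and the ordered-consensus domain check are transparent
  approximations of HMM-based tools, adequate for planted synthetic
  signal but not drop-in replacements on real proteomes.
* The progressive aligner has no iterative refinement; deep or
  gap-heavy families would benefit from an external MSA tool.
* Segmental-duplication calls are identity-based only; no synteny or
  collinearity evidence is used, and no Ka/Ks dating is performed.
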