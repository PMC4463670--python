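# Methods

## Scope and data model

srnakit analyses two single-end small-RNA libraries (called A and B
throughout; in the motivating design these are intermuscular bone and its
surrounding connective tissue). All sequences are held internally in the
DNA alphabet (T, not U) because FASTQ and genome references are DNA;
conversion to RNA happens only in report tables. All coordinates are
0-based half-open internally; 1-based positions appear only in isomiR
substitution reports, which follow the mature-miRNA numbering convention
(seed = positions 2–8).

The pipeline's atom is the *clean tag*: a unique 18–30 nt insert sequence
with a per-library read count. Stages pass tags, not reads, so every
downstream quantity is reproducible from the collapsed FASTA alone.

## Read cleaning

Filters run in a fixed first-failure order — quality, 3′ adapter, polyA,
length — and each raw read is counted exactly once, making the discard
ledger exact: raw = clean + Σ discards. Defaults:

* quality: discard when more than 1 base is below Q20. The threshold is
  conventional for Illumina small-RNA data; both knobs are arguments.
* adapter: the longest exact match of an adapter prefix (≥ 6 nt) anywhere
  in the read marks the insert end; reads with no match, or with the
  adapter at position 0 (empty insert), are discarded. A deterministic
  exact-prefix rule replaces heuristic trimmers and is sufficient for both
  synthetic data and typical high-quality libraries.
* polyA: inserts with ≥ 80% A.
* length: insert outside [18, 30] nt.

Report percentages are computed as numerator/denominator and rounded to
2 decimals at report time only; internal values are never rounded.

## Mapping and annotation

The genome mapper allows at most one substitution (no indels, matching the
short-tag regime). It is a pigeonhole scheme: one of the two halves of a
tag must match exactly, so exact half-matches against a positional k-mer
index propose loci that are verified by Hamming comparison on both
strands. The mapper is checked exhaustively against a brute-force scan in
the tests; a tag counts as mapped if it has ≥ 1 locus, and multi-locus
tags count once in read-level summaries.

Annotation assigns each tag to exactly one category by the priority order
rRNA > scRNA > snRNA > snoRNA > tRNA > repeat > exon > intron >
unannotated; structural RNAs dominate real contamination, and a total
order makes the category table a partition. A tag matches a category when
it is a ≤ 1-mismatch substring of a category reference on either strand;
hit strand resolves the exon/intron sense–antisense split, and the
degraded-mRNA screen is realised as the exon-sense category against a
transcript FASTA. The one-mismatch tolerance is applied to both genome
mapping and annotation (configurable); only unannotated tags proceed to
miRNA analysis.

## miRNA identification and isomiR typing

A tag supports a mature miRNA when it decomposes against it within the
identification gate: 5′ and 3′ end offsets each ≤ 4 nt, at most one
substitution in the overlapping mature region, templated parts lying on
the hairpin. Candidate matures are proposed by a 6-mer index over the
hairpin window around each arm; 6 is the guaranteed length of the longest
clean templated stretch in the worst admissible case (18-nt tag, one
substitution, 4-nt tail), so no gateable tag can be missed. A miRNA is
"identified in a library" at count ≥ 1. Tags whose sequence matches
several mature references are attributed to each and flagged ambiguous.

Decomposition resolves the genuine ambiguity between end shifts and
substitutions by minimal-edit parsimony: minimise |offset5| + |offset3| +
substitutions, ties broken by smaller |offset5| (positive offset first as
a fixed tie rule). The 3′ extension is split into a templated run
(matching the hairpin continuation) and a non-templated tail starting at
the first non-matching base; everything after that base is non-templated
by definition. Every record regenerates its tag byte-exactly
(`reconstruct`), which the tests enforce on all simulated reads.

The substitution spectrum counts unique tags, not reads, so one abundant
variant cannot dominate the 12-type table; this choice (read-weighting is
available via the records themselves) reflects how edit spectra are
usually summarised from aligned unique tags. Only seed-region
substitutions enter the spectrum by default (configurable).

Families are parsed from names by a fixed grammar — strip the species
prefix, the `-5p/-3p` arm suffix, the `*` star mark, then reduce to the
`let-N`/`miR-N` stem — which reproduces the conventional let-7 and
miR-199 groupings. Duplex (miRNA:miRNA\*) pairs are emitted when both
annotated arms of a hairpin have expressed catalog entries; 3′ overhangs
are computed from the arm intervals under the ideal fold pairing
i ↔ H−1−i, which yields the canonical 2-nt overhangs for arms placed by
that geometry.

## Differential expression

NE = count/total × 10⁶ against the library's clean-read total (the
literal reading of the normalisation formula; normalising to miRNA-mapped
totals is a flag). Adjustments run floor → both-below-1 removal →
min-reads removal, in that order, so log₂(NE_B/NE_A) is always defined.
The raw-count floor (default 100, applied as max(x, y) < 100) removes
counts too small to be biologically or technically meaningful in deep
libraries.

The exact test is the Audic–Claverie conditional: y | x ~ NB(x+1,
N_A/(N_A+N_B)). The two-sided p doubles the smaller of P(Y ≤ y) and
P(Y ≥ y), capped at 1. One subtlety is deliberate: naive tail-doubling is
not invariant under swapping the two libraries, so the implementation
canonicalises the conditioning orientation (it conditions on the
lexicographically smaller (count, total) pair) before taking tails. The
statistic is then orientation-free, which the report relies on; the
direct-summation oracle in the tests applies the same canonicalisation.
Tails are evaluated with scipy's negative binomial, and the tests pin
them to term-by-term summation of the conditional distribution at 1e-10
over all x + y ≤ 200 at three total ratios.

Thresholds: |log₂ ratio| ≥ 1 and p ≤ 0.01 by default (the stricter of the
two conventions used for this design; 0.05 is a parameter away). No
multiple-testing correction is applied by default since the method's
lineage reports raw exact-test p-values; Benjamini–Hochberg is available
behind a flag. On discrete counts the exact test is conservative: in the
null-calibration experiment (100 miRNAs, 10⁵ reads/library, 2000
replicates) the pooled fraction of p ≤ 0.05 is ≈ 0.045.

## qPCR validation

Ct values are averaged over replicates by arithmetic mean before any
transformation (the convention for ΔΔCt), ΔCt = Ct_miRNA − Ct_5S uses 5S
rRNA as the reference gene, and ΔΔCt subtracts the ΔCt of a user-chosen
reference tissue (default muscle) — the only reading of the stated
equation that yields a well-defined baseline; the reference tissue is
recorded in the output and its column is identically 1. Clustering is
agglomerative (average linkage) on Euclidean distances of log₂ values,
the most common heatmap defaults, both configurable; missing values are
excluded pairwise from distances with sklearn-style rescaling. Dendrogram
merge heights are permutation-invariant and leaf order is deterministic
given scipy's tie rule.

## Seed-match target scanning

"Perfect or near-perfect complementarity" is operationalised as the
standard site taxonomy: 6mer (complement of positions 2–7), 7mer-m8
(+ position 8), 7mer-A1 (+ A opposite position 1), 8mer (both). Site
positions are reported at the 6-nt core so the type classes nest as
position sets. Whole transcripts are scanned, not just UTRs, because
EST-derived transcript sets lack UTR annotation. No free-energy or
conservation scoring is attempted.

## The synthetic-data generator

The generator emulates the study conditions end to end: hairpin
precursors (default 60, 80 nt) carrying a mature arm (20–23 nt, 10-nt 5′
flank) and, for 30% of hairpins, a star arm placed with the canonical
2-nt 3′-overhang geometry at 5% of the mature's abundance; per-miRNA
abundances are lognormal (σ = 0.8, a typical dynamic range for miRNA
catalogues); 10% of miRNAs are truly differential at |log₂ fc| = 2 with
alternating direction; contaminants total 3% (rRNA 1.2%, tRNA 0.8%,
snoRNA 0.5%, mRNA fragments 0.5%, both strands), matching the ≈97%
retained-for-miRNA fraction typical of size-selected libraries; isomiR
rates are trim5 2%, trim3 5%, templated 3′ extension 3%, NTA 5% (U-heavy
tail weights, 0.8), seed substitution 1% — small but detectable rates in
line with deep-sequencing isomiR surveys; 0.5% of reads are low quality.
Reads are SE50: insert + 3′ adapter + post-adapter filler, constant Q40
qualities except for flagged low-quality reads.

Ground truth records, per read, the parent, signed end offsets, NTA
string, substitutions and contaminant category, and per miRNA the
expected and realized counts and the true log₂ fold change. The first
base of a generated NTA tail is drawn excluding the hairpin-continuation
base, because an addition matching the template is by definition not
observable as non-templated; in the degenerate all-U-weight case where
the continuation is U, the tail is dropped.

What the generator does *not* emulate: position-dependent sequencing
error, ligation bias, 5′ adapter read-through, multi-locus miRNA genes
with shared mature sequences, and RNA folding (star arms come from
annotation geometry, not structure). Passing tests therefore demonstrate
algorithmic correctness and calibration under idealised noise, not
robustness to platform artefacts.

## Problem sizes and numerical choices

Simulation-backed tests run at 2 × 3,000–5,000 reads with 15–30 hairpins,
and the acceptance experiments at 10⁵-read depth (count level) and 10⁴
reads (read level) — sizes at which every binomial/multinomial check has
comfortable power while the whole suite stays fast. Exact-test tails are
computed in scipy's parameterisation without logs (counts ≤ a few
thousand); the oracle uses a cumulative-product recurrence. Ties in tag
ordering are broken lexicographically everywhere, so all tables are
byte-deterministic under a fixed seed.

## Known limitations

* One library per condition: the exact test quantifies sampling noise
  only, not biological variability; calls are "differential sequencing
  frequency", not replicated biology.
* No novel-miRNA discovery; identification is strictly against provided
  mature/hairpin references.
* The mapper allows substitutions only (no indels) and is quadratic in
  genome size at index-build time, sized for surrogate genomes of up to a
  few megabases, not whole vertebrate genomes.
* isomiR calls cannot distinguish true editing/tailing from sequencing
  error; the spectrum is descriptive.
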