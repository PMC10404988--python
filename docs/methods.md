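# Methods

## Scope and model

`v9var` quantifies apparent intragenomic variability of the V9 hypervariable
domain of the eukaryotic 18S rRNA gene (~104–137 nt) and how the choice of
OTU definition — single-linkage clustering at one difference ("swarms"),
greedy centroid clustering at 97% identity, or model-based denoising into
amplicon sequence variants (ASVs) — inflates or deflates diversity
estimates. The apparent variability in a genome or transcriptome has three
sources: genuine rRNA copy polymorphism, sequencing error, and
contamination. The pipeline separates them with (i) a quality-dependent
divisive denoiser, (ii) identity-to-top-unit contamination rules, and
(iii) two clustering definitions whose outputs can be compared per taxon.

All experiments run on synthetic data whose generator encodes the
assumptions the analysis makes; nothing here depends on network access or
external databases.

## Alignment and identity

One percent-identity definition is used everywhere (extraction screening,
centroid clustering, contamination rules, annotation, similarity levels):
the optimal global alignment under match +1, mismatch −3, and affine gaps
costing `5 + 2·L` for a gap of length L; identity = identical columns /
total alignment columns, gaps included.

Numerical choices:

- All scores are integer-valued, so the dynamic program is exact in float64
  and tie detection is safe.
- Traceback is deterministic: on ties prefer the aligned-pair state, then
  the gap consuming the first sequence, then the other gap.
- Because co-optimal alignments can differ in column count, identity is
  defined on the lexicographically ordered pair of inputs (by length, then
  sequence); this makes `identity(a, b) == identity(b, a)` exact.
- The banded variant (default half-width 16) escalates its band until a
  certificate holds: any path leaving a band of half-width w needs at least
  `|Δ| + 2w + 2` gap columns, bounding its score by
  `min(n,m) − w − 1 − 2·gap_open − gap_extend·(|Δ| + 2w + 2)`. When the
  banded score reaches that bound the result provably equals the full
  matrix; otherwise the band doubles (worst case: full matrix). Near-identical
  pairs — the common case inside the denoiser — certify at the first band.

## Reference database and extraction

V9 references are located per full-length 18S sequence by scanning for the
universal primers 389F (`TTGTACACACCGCCC`) and 1510R
(`CCTTCYGCAGGTTCACCTAC`) with an IUPAC-aware ungapped mismatch count, up to
5 substitutions per primer (degenerate primer bases match their expansions;
degenerate subject bases get no credit). The V9 region is the segment
strictly exclusive of both primer footprints; when several sites pass, the
lowest-mismatch then leftmost forward / rightmost reverse pair wins. If the
pair is absent on the given strand the reverse strand is tried and the
result is reported in the record's own orientation. Indels within primer
sites are not modeled.

Read-level extraction aligns each reference into the read with an infix
(glocal) alignment — reference covered end to end, read ends free — which
operationalizes the "first to last reference nucleotide" full-span rule by
construction. The best-identity reference wins (ties to the smaller id) and
hits below 80% identity are rejected. The infix search uses edit-distance
alignment for speed; its path identity tracks the affine-gap definition
within 0.005 on V9-scale sequences (asserted by test).

## Read preparation

- Mean-quality filter: reads with arithmetic mean Phred < 20 are removed
  (a read exactly at 20 is kept).
- Pair merging: best ungapped overlap (≥ 20 nt, ≤ 10% mismatches) between
  the forward read and the reverse-complemented mate; disagreeing columns
  resolve to the higher-quality base, merged quality is the per-column max
  (conservative and bounded by the Phred scale, rather than summed).
- Amplicon primer trimming is substitution-only (no indels) at ≤ 20%
  mismatch fraction; pairs lacking a 5′ primer are discarded, trimmed mates
  under 50 nt are discarded, and 3′ read-through primers are recognized down
  to 4-base suffix overlaps. Partial 5′ primer occurrences are not emulated.
- The pre-denoising filter truncates at the first base under `truncQ`,
  crops to `truncLen` (discarding shorter reads), and removes reads with
  any N or with expected errors `Σ 10^(−q/10)` above the cap (default 2).
- Adapter trimming is a pluggable no-op: synthetic reads carry no adapters.

## The divisive denoiser

Reads are dereplicated into uniques carrying positionwise mean qualities
(a unique-level aggregate keeps cost at desk scale; read-level qualities
change nothing for constant-quality profiles). For unique j in a partition
with center c holding N_c reads,

    rho_j = Π_cols P(c_base → j_base | q),   lambda_j = rho_j · N_c,
    p_j = P(X ≥ n_j | X ≥ 1),  X ~ Poisson(lambda_j),

with p ≡ 1 for singletons, so a singleton can never seed a new partition.
While min p < Ω_A (default 1e−40, the conventional partition-split
threshold, which reproduces the singleton behavior the tests rely on), the
most significant unique becomes a new center and every unique is
reassigned to its most probable center. Probabilities are computed in log
space; alignments against centers use the gapless fast path when lengths
match and at most 6 substitutions separate the pair (provably optimal under
this scoring), otherwise the banded aligner, with a configured per-gap-column
indel probability (default 1e−5).

Error-model learning alternates denoising with re-estimation of the
(from, to, quality) substitution rates from unique-vs-center mismatches,
weighting by unique counts; empty quality bins inherit the nearest observed
bin; each off-diagonal rate is regularized to be monotone non-increasing in
quality by isotonic regression (the same shape constraint as loess-based
smoothing, without a smoothing-span parameter) with a probability floor of
1e−7; iteration stops when the transition matrix moves < 1e−6 in max-norm
(at most 10 rounds). The quality-nominal model (`10^(−q/10)` split evenly
across the three off-diagonal targets) is both the initial condition and
the default model when none is learned.

Bimera removal (consensus): an ASV is flagged in a sample when it equals a
left-prefix of one parent plus a right-suffix of another (one breakpoint,
zero mismatches), both parents ≥ 2× more abundant; it is removed globally
when flagged in more than 90% of the samples where it was testable (≥ 2
candidate parents present).

Paired mode truncates both mates to 80 nt, denoises the two streams
independently, merges denoised mate pairs by exact ungapped overlap of
≥ 12 nt, and removes bimeras. A real limitation follows from the merge
rule: templates longer than `2·truncLen − 12` produce non-overlapping
denoised mates and are dropped entirely; in particular a template stretch
covered by neither mate cannot occur among merged ASVs, so "hidden middle"
variants are unrepresentable rather than silently collapsed.

## OTU definitions

Swarms are connected components of the Levenshtein-distance-≤1 graph over
unique sequences, seeded by the most abundant member. Neighbor candidates
come from deletion-signature hashing (each sequence indexed under itself
and all single-deletion variants), with an O(len) structural verification
per candidate pair; the all-pairs graph is retained as the test oracle.
The fastidious refinement grafts each swarm of mass < 3 onto the
highest-mass swarm (if any) reachable through one virtual intermediate
(distance ≤ 2 between any member pair, checked with edlib); graft targets
are fixed before merging so light swarms cannot chain. Output is
canonicalized (mass-descending, seed-lexicographic; members
count-descending) so input order is irrelevant. Swarm breaking is not
implemented; note that the swarm count is not monotone in the fastidious
boundary (raising it also shrinks the set of heavy graft targets), so only
"grafting never increases the count" is guaranteed and tested.

Centroid clustering is the greedy size-ordered pass: each sequence, in
decreasing count order, joins the first existing centroid at ≥ 97% global
identity or founds a new cluster.

The environmental prefilter retains barcodes present in ≥ 2 samples with a
total of ≥ 3 reads.

## Contamination rules

Units are ranked by count; the most abundant is the reference point.
Barcodes below 80% identity to the top barcode are classed as
foreign-phylum contamination; ASVs below 90% identity to the top ASV as
putative contaminants; everything else is retained intragenomic
variability. Barcode-level removal precedes OTU/ASV inference. Same-phylum
contamination is inherently invisible to these rules.

## Synthetic data generator

A simulated genome draws a random dominant V9 template (default 123 nt,
within the observed 104–137 span) and k−1 minor variants at exactly the
configured substitution distance (default 2), weighted by the copy-weight
vector. Each read copies its template and applies quality-dependent
substitutions (default: the Phred-nominal rate at constant q=30, i.e.
1e−3) followed by uniformly placed indels (default rate 0). Contaminant
reads copy a rejection-sampled unrelated template below 0.75 identity to
the dominant variant; configurations whose minor variants would approach
the contaminant band (within 0.05) are rejected. Chimeras concatenate two
variant templates at one uniform breakpoint ≥ 10 nt from either end,
matching the two-parent model the bimera test assumes. Default depth is
1000 reads. A truth table partitions every read into variant /
contaminant / chimera with its template index.

Environmental communities follow a power-law rank-abundance curve
(`p_i ∝ i^−1.8` by default) sampled multinomially per sample (defaults:
4 samples × 5000 reads over 50 taxa); the emitted table lists observed
barcodes only, like a real dereplicated table, while the truth keeps all
templates. Two rare taxa (one single-sample singleton, one with 2 reads
total) are planted so the prefilter always has work to do.

What the generator does not emulate — and what passing tests therefore do
not establish for real data: PCR amplification bias, tag jumping,
platform-specific error motifs, quality-score miscalibration, length
heterogeneity of real V9 loci within a genome, and same-phylum
contamination.

## Problem sizes and determinism

The test suite and the acceptance script run the full stack on: 100 random
swarm instances of up to 200 uniques; 1000 alignment pairs; 20 seeds per
variant count k ∈ {1,2,3} at depth 1000 for denoiser recovery; 20 seeds for
contamination recovery; 20 noisy taxa for the protocol comparison; and 5
sources for environmental matching — sizes at which every stochastic
property has margin while a complete run stays in the low minutes.
Every random draw flows from an explicit seed (the acceptance script
spawns per-section seeds from `--seed`), and identical seeds give
byte-identical FASTQ and identical metric tables.

## Known limitations

- The denoiser is not a bit-exact reimplementation of any published tool;
  pooling/prior options, homopolymer-aware models and E-values are out of
  scope.
- Swarm clustering supports d=1 only.
- find_v9 identity is edit-distance-path based (within 0.005 of the affine
  definition); extraction at the 0.8 boundary can differ for reads sitting
  exactly on it.
- The worked-example FASTA is a synthetic stand-in (125 nt, two
  substitutions, counts 93/86) for a published barcode pair that is not
  redistributable here; it exercises the scoring scheme, not the original
  sequences.
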