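# Methods

This note documents the models, conventions and numerical choices
behind `gted`, in the order data flows through the pipeline.

## Library geometry and what the simulator emulates

The assay enriches fragments that span one terminus of one LTR
retrotransposon insertion: a nested PCR anchors one primer inside the
LTR and the other on the sequencing adapter, so after indexing, R2 reads
TE sequence adjacent to the element terminus and R1 reads the flanking
genomic DNA toward the element, from a fragmentation-randomised start.

The simulator (`gted.simulate`) reproduces exactly this geometry on a
uniform-random reference:

- **Insertions** are full-length consensus copies planted in either
  orientation with a target-site duplication (`tsd_len`, default 4 bp —
  typical for LTR elements; the paper trail of coordinates accounts for
  it: the left breakpoint sits at the insertion position *p*, the right
  one at *p − tsd_len*).  Sites are uniform over positions ≥ 400 bp from
  contig ends with ≥ 600 bp spacing (twice the flank window) enforced
  across the whole cohort, so flank windows of distinct junctions never
  collide.
- **R2** covers the terminal `read_len` bases of the consensus on the
  strand the nested primer implies (reverse-complement at the 5′
  terminus, forward at the 3′).
- **R1** reads per junction: a fraction `straddle_frac` (default 0.8)
  straddle the breakpoint, with genomic offsets drawn *without
  replacement* from `read_len/3 .. 2·read_len/3` — distinct start
  positions are therefore guaranteed, and both the genomic and TE
  segments stay long enough (≥ 25 bp at the 75 bp default) to seed a
  local alignment.  The remainder start `read_len .. 300` bp into the
  flank and contribute only to window counts.  The straddling count is
  deterministic (`round(straddle_frac × pairs_per_junction)`), not
  binomial: the desk-scale fixtures are meant to probe the calling
  logic at a stated depth, not depth sampling noise.
- **Background**: 5% of pairs (configurable) are drawn anywhere in the
  genome with a non-TE R2, exercising the UNASSIGNED demultiplex path.
  A sample can also be all-background (the non-target-species control).
- **Replicates** share the genotype and differ only by read seed and an
  optional depth jitter; related sublines copy a fraction of another
  line's insertion set.
- Reads carry uniform substitution errors at `error_rate` and constant
  Q30 qualities.  Defaults: `read_len = 75` (paired-end 150-cycle
  chemistry), 20 pairs per junction.

What the simulator does **not** model: PCR duplicates and chimeras,
indel sequencing errors, quality-score profiles, enrichment-efficiency
variation between junctions, and diverged genomic TE copies (planted
copies equal the consensus).  Passing tests therefore demonstrate the
correctness of the calling/profiling/classification logic under the
stated read geometry, not robustness to every artifact of real
libraries; real-data users should treat the aligner and masking
defaults as replaceable (pre-masked references and external SAM input
are first-class paths).

The synthetic TE families are 1500 bp (250 bp LTRs).  Real LTR copies
are identical within an element; here the 3′ LTR carries one
substitution every 25 bp relative to the 5′ copy so that the LTR of
origin of an R2 read — hence the junction side — is computable from its
best alignment.  This is a synthetic-construction convenience, and the
side-consistency check in junction calling tolerates co-optimal hits to
the homologous other-LTR copy by testing every returned TE alignment.

## Masking

`mask_reference` N-masks every exact occurrence (both strands, ≥
`min_match_len` = 100 bp, floor 20) of consensus sequence, by k-mer
seeding plus maximal exact extension.  Exact matching is sufficient for
synthetic genomes; diverged real copies require an externally masked
FASTA.  Masking is idempotent (already-masked input passes through) and
never changes contig lengths.

## Local alignment

Affine-gap local alignment (Gotoh recurrences) with match +2,
mismatch −3, gap open −5, gap extend −2; a gap of length k costs
open + (k−1)·extend.  N never matches.  These values are a declared
convention of this package, not taken from any publication.  Two search
modes share the scoring kernel:

- *exhaustive*: full DP against every target (used automatically when
  the target set is ≤ 8 kb — exactness on arbitrary inputs matters
  there, e.g. for oracle comparisons);
- *seeded*: exact 15-mer seeds looked up in a sorted index, diagonal
  clusters expanded into padded windows, DP per window.  Guaranteed to
  find any alignment containing one exact seed; pipeline reads are
  target-derived, so the stages request this mode explicitly.

Alignment ends are recovered without traceback storage via the
reversed-prefix trick; among co-optimal ends the first in row-major
order wins, and among co-optimal starts the shortest alignment —
deterministic, and irrelevant to scores.  The second-best score is the
best alignment at a *distinct locus* (other target, other strand, or
start offset > read length); `filter_unique_best` keeps a read only if
its best score strictly exceeds it, so ties are dropped.

## Junction calling

Demultiplexing assigns each pair to the family of its R2's best
consensus alignment at a score floor of 0.6 × read_len × match; family
score ties go to UNASSIGNED.  The junction stage aligns R1 both to the
masked genome and to the consensi at a lower floor (0.3×): a split
read's two segments each cover only part of the read, and the nominal
floor would make a 60/40 split undetectable.

A read passes the congruence test when its genome- and TE-aligned query
intervals are non-nested and jointly account for the read: unexplained
bases (gap between intervals plus uncovered ends, overlap credited)
≤ `slack` = 2.  Overlap between the intervals is genuine biology-plus-
alignment behaviour — micro-homology at the junction lets the genome
alignment extend a few bases into the element, occasionally with a
spurious gap — and is tolerated up to 25 bp (a third of the default
read); far larger overlaps suggest chimeras.  The TE alignment must
reach the consensus terminus named by the R2's LTR (±6 bp).

The breakpoint is obtained by projecting the TE-alignment query
boundary through the genome alignment **from its junction-distal end**,
which sits in clean genomic sequence; this makes the coordinate immune
to end trimming and micro-homology over-extension, and exact on
noise-free data.  Residual risk: a chance extension that swallows the
entire TE segment would make the intervals nested and reject the read;
this needs ~60% identity over ≥ 25 bp and has not been observed across
seeds.

Support is pooled over all samples of a run; breakpoints within
`merge_window` = 3 bp (same contig/side/family/direction) collapse by
single linkage to the modal position, ties to the smaller coordinate.
The validity filter is the conjunction **n_reads ≥ 12 AND distinct R1
start positions ≥ 4** (both configurable); "start" means the
strand-aware 5′ end of the retained genome alignment, matching the
fragmentation-randomised geometry.  Distinct starts are counted over
the pooled support of a junction, consistent with pooled
identification.  Only breakpoint-spanning reads count as support;
window-resident reads enter later at quantification.

Flank windows are the ≤ 300 bp of genomic sequence immediately outside
the junction (left of the breakpoint when the element lies rightward,
right of it otherwise), truncated at contig bounds.  The 5′ and 3′
junctions of one insertion are kept as separate markers.

## Profiling

The count for (junction, sample) is the number of retained
(uniquely-mapped, family-matched) R1 alignments whose strand-aware
start falls in the window; a read starting in two abutting windows
counts in both.  Depth control: `subsample_pairs` draws a uniform
sample without replacement (membership decided on sorted read ids, so
it is input-order independent); the pipeline default of 10 million
pairs is a real-data control and is effectively a no-op on fixtures.

Normalization is counts-per-million by per-sample mapped-read totals
(the count of retained, family-binned R1 alignments).  The original
normalization is not specified beyond its existence, so CPM is this
package's choice, exposed as a strategy (`cpm` |
`total-junction-reads` | `none`).  A sample with a zero total cannot be
normalized; the pipeline carries such samples as all-absent profiles
(they always identify as NO_ID) rather than failing the whole run.

Binarization follows the dummy-zero z-score rule: for S samples append
S zeros per junction row, compute z with the population σ of the 2S
values, and call "present" iff z > 0 strictly (z = 0, in particular the
all-zero row, is absent).
The σ convention (population vs sample) cannot change the sign of z,
hence not the call; population σ is used and recorded.  Algebraically
the rule is x_i > Σx/(2S), and the tests verify this equivalence
against a literal augmented-vector computation.

## Clustering and identification

Columns of the 0/1 matrix are clustered with Euclidean distance and
complete linkage by default (the defaults of the common heatmap
routine for such figures); Jaccard distance and average/Ward linkage
are options.  scipy's linkage is deterministic given input order; its
tie-breaking is order-dependent, so tree topology is guaranteed
permutation-invariant only when pairwise distances are tie-free (no
index-based rule can do better).  Dendrograms export to newick with
branch lengths from merge heights; heatmaps are dendrogram-ordered.

Signatures are consensus junction-key sets per line: keys present in ≥
2/3 of replicates (a single mislabeled replicate therefore cannot
corrupt a signature; single-replicate lines use that replicate).
Identification computes Jaccard similarity — with the same ±3 bp
breakpoint tolerance used when merging candidates, to absorb cross-run
coordinate jitter — against every stored line and calls the argmax iff
similarity ≥ τ; otherwise NO_ID with BELOW_SIMILARITY, AMBIGUOUS on a
tie, or TOO_FEW_JUNCTIONS when fewer than `min_junctions` junctions
were detected at all.  **τ = 0.6 and min_junctions = 50 are conventions
of this package** (the original identification was by dendrogram
inspection); they are chosen so that sublines sharing half their
insertions (pairwise Jaccard ≈ 1/3 between signatures) remain separable
while foreign or empty profiles can never match, and both are mandatory,
reported parameters of every result.

Passage stability is assessed with a label-permutation test on
cophenetic distances (statistic: mean between-batch minus mean
within-batch distance; 999 permutations, +1-corrected p).  p > 0.05
means no batch structure — the expected outcome when repeated
resamplings of one genotype are labeled by "passage".

## Determinism and problem sizes

Every source of randomness takes an explicit seed; cohort generation
derives per-sample seeds from one master seed via `SeedSequence`.  Full
pipeline runs are byte-identical given identical configuration, and
every text output is stamped with the configuration checksum (the
output directory is excluded from the checksum so runs into different
directories compare equal).

The bundled test and acceptance cohorts use 5 active families × 10
insertions per line on 30–400 kb references, triplicate samples, 20
pairs per junction and 0–2% substitution error — sizes chosen so the
whole suite exercises every stage, including two full cohort analyses,
in a couple of minutes on one CPU.  All reported quantities (recovery,
ARI, identification accuracy, p-values, oracle agreement) are computed
by the tests and the acceptance script at run time.

## Known limitations

- Exact-match masking misses diverged genomic TE copies; supply a
  pre-masked reference for real genomes.
- The built-in aligner targets desk-scale references (≲ 10 Mb); use an
  external aligner plus SAM ingestion beyond that.
- No genotyping of zygosity or insertion frequency; junctions are
  treated as binary markers.
- No mixture/contamination deconvolution: a low-level contaminant
  shifts few windows and will not change calls.
- The identification thresholds were calibrated on synthetic cohorts;
  real signature databases should re-examine τ against their observed
  between-line similarity distribution.
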