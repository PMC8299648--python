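# Methods

## Overview

`scapa` analyses alternative polyadenylation (APA) from 3'-tag single-cell
RNA-seq.  These protocols prime reverse transcription on the poly(A) tail,
so read 3'-ends pile up just upstream of cleavage-and-polyadenylation
sites.  The pipeline has five stages: (1) preprocessing of raw reads into
deduplicated per-molecule 3'-end tags, (2) poly(A)-site calling from the
pooled poly(A)-tagged 3'-ends, (3) peak-region definition and per-cell
isoform counting, (4) cell-type specificity scoring of per-gene usage, and
(5) modality classification of the distal-usage distribution across
cells.  A simulator generates inputs with known truth for every stage.

## Preprocessing

Read1 carries the cell barcode and UMI at declared offsets; both are moved
onto the read2 name (suffix `_CB:<bc>_UB:<umi>_PA:<0|1>`) so any aligner
passes them through, and are additionally written as `CB`/`UB` aux tags
with the poly(A) flag as `XA:i` when alignments are emitted directly.
A read containing a run of >= 8 consecutive adenines is truncated at the
start of the **first** such run (anything 3' of the tail start is tail or
adapter) and flagged `polyA`; trimmed reads shorter than 20 nt are
discarded.  `N` never counts toward an A-run, and runs are matched
exactly — no mismatches are tolerated, since a permissive matcher would
also truncate genuinely templated A-rich sequence.

After external alignment (any spliced aligner; the package consumes
coordinate-sorted SAM/BAM), only primary records with mapping quality
>= 20 are admitted as "uniquely mapped" — the MAPQ floor is configurable
because different aligners encode uniqueness differently.  PCR duplicates
collapse on (cell barcode, UMI, chromosome, strand, 3'-end coordinate);
the 3'-end is the rightmost aligned base on `+` and the leftmost on `-`
(read2 is assumed sense; an `antisense` switch flips this).  If any
duplicate carries the poly(A) flag the surviving molecule does, which
makes deduplication order-invariant and idempotent.

## Poly(A)-site calling

Poly(A)-flagged tag 3'-ends are pooled (per cell type when types are
analysed separately) and piled up per single-nucleotide position.  By
default only positions inside annotated same-strand 3'UTRs are considered
(3'UTR = exonic sequence 3' of the CDS end; terminal exon for transcripts
without CDS); disabling the restriction admits intronic and intergenic
candidates.

**Internal priming.**  Oligo-dT can prime on genomic adenine stretches,
creating artifactual 3'-ends.  A candidate position is removed when the 20
nt immediately downstream (transcription direction; reverse-complemented
on `-`) contain >= 6 consecutive adenines.  The filter is monotone in the
run threshold and errs on the side of discarding true sites inside A-rich
context, a known cost of heuristic filters.

**Clustering and thresholds.**  Surviving positions are clustered by
single-linkage with a 20 nt gap (a chain of gaps <= 20 joins one
cluster).  Clusters need >= 3 raw tags and >= 1 tag-per-million of the
library-wide deduplicated poly(A)-tag count; both thresholds are exposed
because no canonical values exist.  The cluster summit (maximum count;
ties break to the 5'-most position in transcription direction, a
deterministic convention favouring upstream cleavage heterogeneity) is
reported as the site.

Sites are classified against an annotated set by signed distance in
transcription direction to the nearest same-strand annotated site;
|distance| <= 24 nt marks a site as annotated, the remainder as novel
(24 nt is the clustering radius used by poly(A)-site databases).  Site
sets called per cell type merge by single-linkage at the same radius,
keeping the highest-count summit as representative.  The AATAAA signal is
profiled over +/-50 nt of each site; for genuine sites the occurrence
frequency peaks ~21 nt upstream.

## Peak regions and quantification

Peaks are built from the 3'-ends of **all** deduplicated tags, not only
poly(A)-flagged ones, because the read body upstream of a site is part of
its peak; a `polya_only` switch restricts to flagged tags.

**Parametric density clustering.**  For a pileup on one (chromosome,
strand), score a contiguous segment S at density parameter d as
`score(S, d) = total_tags(S) − d · span(S)`.  A segment is a cluster over
the density interval (d_min, d_max]: d_max is the weakest-trim density
(the smallest d at which removing some prefix or suffix stops hurting the
score) and d_min is the break density of its parent in the nest.  The
implementation computes the nest recursively by splitting each segment at
its weakest trim; a brute-force enumeration of all subintervals serves as
the test oracle.  Reported clusters need total >= 10 tags, span <= 200 nt
and stability d_max/d_min >= 2; within a nest only the largest passing
cluster is kept.  Root clusters take d_min equal to their own overall tag
density rather than 0 — a root's stability is otherwise undefined
(infinite), and because the weakest trim of a multi-position segment is
always below its overall density this convention means diffuse top-level
segments (e.g. uniform coverage) are never reported as stable peaks,
while an isolated single-position spike still is.

Per-cell-type peak lists are merged by interval union (bookended
intervals merge).  Peaks keep >= 1 bp same-strand overlap with a gene
body (GTF `gene` records, else transcript union).  Each peak is assigned
exactly one site: a peak containing k >= 2 sites splits at the
minimum-pileup position between adjacent sites (ties resolve toward the
midpoint); a siteless peak is rescued by the nearest site within 50 nt of
its edges, else dropped.  Disjoint peaks assigned to one (gene, site) —
typically a summit peak plus a rescued fragment — count as one isoform.

UMIs are counted per cell per isoform over half-open peak intervals.
Usage is `U_ig = C_ig / Σ_i C_ig`, defined only where the gene has
non-zero total in the cell (NA otherwise); defined vectors lie on the
simplex to 1e-9.  Gene expression is normalised to unique transcripts per
million (uTPM; per-cell sum 1e6) with a `log2(uTPM + 1)` view.

## Cell-type specificity

Per gene, usage vectors of the detecting cells are compared by Hellinger
distance `d(u, v) = (1/√2)·‖√u − √v‖₂ ∈ [0, 1]`; `S = 1 − d` defines a
cell–cell similarity network.  Specificity is scored by cross-validated
neighbor voting: per repeat (10 by default) cells are split into 3
stratified folds; each hidden cell votes for type t with its total
similarity to training cells of type t divided by its total similarity to
the whole training set (0.5 when the denominator vanishes — degree
normalisation makes votes scale-invariant), and the vote ranking against
true one-vs-rest membership gives a Mann–Whitney AUROC with midranks for
ties.  The mean over folds and repeats is reported per type with >= 10
detected cells; everything is deterministic given the seed.  Genes with
AUROC strictly above 0.8 are called cell-type specific.

As corroboration, a one-vs-rest differential-usage test runs on
artificial bulk: isoform counts summed over the type's cells vs all other
cells form an isoforms × 2 contingency table per gene, tested by
chi-square without continuity correction (Fisher's exact test for 2×2
tables with any expected cell < 5), BH-corrected across genes within a
type.  The test assumes multinomial sampling of the bulk table; when
cells of a gene differ in their underlying usage (finite Dirichlet
concentration in the simulator) the aggregation is over-dispersed and the
nominal type-I level is exceeded — the calibration check therefore runs
on a null with one fixed usage vector per gene, which is the regime the
test is exact for.

## Modality

Per gene and cell type (>= 10 detecting cells), the distal-site usage
(the 3'-most site in transcription direction; for > 2 sites, that single
site's usage) is binned into [0, 1/3], (1/3, 2/3], (2/3, 1] — boundary
values fall into the lower bin — and the binned distribution is compared
by base-2 Jensen–Shannon divergence (bounded [0, 1]) to five references:
proximal (1,0,0), middle (0,1,0), distal (0,0,1), bimodal (½,0,½),
multimodal (⅓,⅓,⅓).  The closest reference gives the label; exact ties
resolve in the order distal, proximal, middle, bimodal, multimodal.  Each
reference maps to itself (fixed points), and the assignment is invariant
to cell order.

Bimodal genes — two cell subpopulations preferring opposite sites — have
the largest cross-cell usage variance and can demarcate subpopulations:
Pearson correlation between every gene's log2(uTPM+1) expression and the
target gene's distal usage (over cells with defined usage; zero-variance
genes excluded) selects the top-50 correlated and top-50 anticorrelated
genes, and average-linkage hierarchical clustering (Euclidean, on
z-scored expression of the selected genes) cuts the cells into two
groups.

## Simulator

The generator's defaults are the study conditions every recovery claim is
made under:

* **Reference** — 10 genes alternating strands, 2 sites per gene, 600 nt
  3'UTR after a 200 nt upstream region, 200 nt intergenic spacers.
  AATAAA is planted at −21 ± 3 nt (uniform jitter) upstream of each site
  on the sense strand; one 10-adenine decoy run per gene sits inside the
  3'UTR >= 50 nt from any site.  Background sequence is uniform ACGT with
  adenine runs >= 4 broken, so only planted decoys can misprime and no
  true site is lost to the internal-priming filter by chance.
* **Cells** — per gene and cell the usage vector is Dirichlet around the
  gene's mean (concentration 10; `inf` yields fixed usage), UMI totals
  are Poisson with mean 30 per gene per cell, and the isoform split is
  multinomial.  "Specific" genes shift their distal mean by 0.4 (0.3 →
  0.7) in one focal type; bimodal genes draw distal means 0.15 / 0.85
  from the cell's subpopulation; expression-program genes are
  single-isoform markers with subpopulation-dependent Poisson rates
  (8 vs 40).  Modality generators follow beta families: distal
  Beta(8,1), proximal Beta(1,8), middle 1/3 + Beta(8,8)/3, bimodal an
  equal mixture of Beta(8,1) and Beta(1,8), multimodal Uniform(0,1).
* **Reads** — one read2 per UMI: 70% end at the site (3' jitter −2..+2
  with mode 0, so the summit recovers the exact site) with a 12 nt
  templated tail; 30% end 20–150 nt upstream without a tail (the peak
  body); internal-priming molecules arrive at 10% of each gene-cell's
  depth, ending immediately 5' of a decoy run whose genomic adenines
  mimic a tail.  A truth SAM with correct alignments and `CB`/`UB`/`XA`
  tags is written alongside the FASTQ so the pipeline can be exercised
  without an external aligner.

What the simulator does **not** emulate: sequencing errors beyond an
optional uniform substitution rate, barcode errors, doublets, ambient
RNA, splicing (reads are unspliced 3'UTR fragments — downstream logic
only consumes 3'-end coordinates), and gene-dense genomes with
overlapping transcription.  Passing recovery tests therefore demonstrate
the correctness of the algorithms under clean geometry, not robustness to
every artifact of real libraries.

## Numerical and evaluation choices

* Coordinates are 0-based half-open internally; BED output uses
  single-nucleotide half-open intervals; GTF I/O converts from/to 1-based.
* Usage-fidelity for the end-to-end check compares pipeline usage with
  the usage implied by the true simulated counts (per-isoform mean over
  cells).  Per-cell usage at 30 UMIs carries irreducible multinomial
  noise (~0.07 mean absolute deviation at u = 0.5), so accuracy claims
  for the counting pipeline are made at the level the pipeline actually
  controls: which peak a molecule is counted in.
* AUROC uses midranks, making it invariant to monotone transforms of the
  votes; folds with no positive or no negative hidden cell are skipped.
* JSD inputs must sum to 1 within 1e-6; `0·log(0/x)` is treated as 0.
* The per-gene network excludes NA cells entirely — a cell that does not
  detect a gene contributes neither votes nor AUROC denominator.
* Problem sizes in tests (200 cells × 10 genes for reads; 200 genes × 4
  types for specificity; 5 × 40 genes × 100 cells for modality) are the
  smallest at which the recovery targets are statistically comfortable,
  keeping the default suite fast on one CPU.

## Known limitations

Heuristic internal-priming filtering cannot separate true sites inside
A-rich sequence from artifacts; peak definitions depend on the paraclu
stability parameters, and very diffuse cleavage regions may be reported
as summit-only peaks; the differential-usage test over-rejects under
cell-level usage heterogeneity (see above); barcode error correction is
limited to exact whitelist matching; and no EM reassignment of
multimapping reads is attempted.
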