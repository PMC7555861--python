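# Methods

This note documents the models and procedures implemented in `rcatseq`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and end conventions

All coordinates are 0-based, half-open (BED convention); single-base ends
are emitted as `[pos, pos+1)`. For a 5′-tagged read the transcript end is
the 5′-most aligned base in transcript orientation; for a 3′ read it is the
last templated base before the poly-A. The template-switch-derived `GGG` is
retained on trimmed 5′ reads by default and treated as soft-clip by the
aligner, so the reported end is the first genome-matching base; a
configuration flag removes it instead. Tag search allows 0 mismatches by
default (configurable to 1). Poly-A trimming removes the maximal trailing
A-run; an optional tolerant mode permits one non-A interruption when the
run resumes for at least `polya_min` bases. rRNA-like exclusion regions are
supplied as a BED file; there is no built-in rRNA database.

## Peak calling

`call_peaks` reimplements distance-based tag clustering: a position seeds a
cluster when its signal reaches `threshold` (default 3, interpreted as
tags-per-million when `threshold_is_tpm`) in at least `nr_pass_threshold`
samples (default 1); adjacent seeds on one contig and strand merge when
their gap is ≤ `max_dist` (default 20 bp, inclusive, single linkage).
Cluster spans cover seeds only; sub-threshold positions inside a span
contribute to the total pooled signal and may carry the dominant position
but can neither seed nor extend a cluster. The dominant position is the
argmax of pooled TPM; ties resolve to the 5′-most position in transcript
orientation (the tie rule is this package's choice — upstream reference
implementations do not document one). Width-1 clusters are dropped only
when `remove_singletons` is set and their signal is ≤
`keep_singletons_above` (default off / 10). The per-sample threshold is
evaluated on per-sample TPM before pooling; dominance uses pooled signal.
Correctness is checked against an O(n²) transitive-merge oracle on random
tracks.

The benchmark calls peaks on data pooled per cell population (the
multi-sample track has one column per population); per-cell calling remains
available through `pool_samples`.

## Feature groups

* **distribution** — total and dominant signal, width, number of covered
  positions, dominant fraction, the dominant position's relative location
  within the assigned gene span (0 = annotated 5′ end, 1 = 3′ end, 0.5 when
  unassigned), log10 total signal, plus one total-occurrence count per
  motif. Heavy-tailed signal columns are quantile-normalized (rank/n
  against the stored training values); bounded counts are min-max scaled;
  fractions and flags pass through.
* **motif** — positional occurrence blocks. Offset *k* ∈ 1..50 is 1 when a
  motif occurrence *starts* (5′-most base, transcript orientation) exactly
  *k* nt upstream of the dominant position; occurrences must fit inside the
  50 nt window, so offsets smaller than the motif length are structurally
  zero. TSS motifs (BREu/TATA/BREd) allow up to 2 mismatches under IUPAC
  semantics; the 13 PAS hexamers are matched exactly (the mismatch
  allowance belongs to the promoter motifs only). Because the PAS lies
  10–30 nt upstream of the cleavage site, the TES window defaults to the
  50 nt upstream of the dominant position; a centered ±25 nt mode is
  available. Windows truncated at contig edges are padded with `N`, which
  never matches.
* **artifact** — for TES peaks, the A fraction and longest A-run in the
  20 nt genomic window downstream of the cleavage site plus a flag for
  A-fraction ≥ 0.6 (internal-priming evidence); for TSS peaks, the G
  fraction and GGG presence in the 3 nt at the start site and the upstream
  C fraction (template-switch evidence). Fractions use available (non-N)
  bases only.

The exact membership of the distribution group is a documented
reconstruction; the fixed list above is the package's contract. The fitted
normalization is stored with the matrix (and inside trained models) and
re-applying it to the training data reproduces the matrix exactly.

## Classification protocol

Peaks are labeled TRUE when the dominant position lies within a tolerance
(default 50 bp, configurable — reference catalogs do not define a matching
window, so this default is flagged prominently) of a same-strand reference
end. Training uses a stratified 70/30 split and five-fold cross-validated
selection in two rounds: a coarse grid, then a fine grid built around the
coarse optimum (RF: trees/depth; LR: C log-grid; SVM-RBF: C/γ; KNN: k),
followed by a final fit on the whole training split; everything is
deterministic given the protocol seed. Class imbalance is handled by
stratified splitting only — no reweighting. Models carry their
feature-column contract and normalizer and refuse mismatched matrices, so
cross-dataset transfer reuses the training normalization. Group ablation
retrains from scratch without one group at a time and reports the accuracy
drop on the held-out split.

## Isoform analysis

A peak belongs to a gene when its dominant position lies between 2 kb
upstream of the annotated TSSs and 2 kb downstream of the annotated TESs on
the gene's strand; overlapping windows are resolved by the nearest
annotated end of the peak's end type. Unassigned peaks are novel-gene
candidates; assigned peaks within the tolerance of an annotated same-type
end are known ends, otherwise novel ends of known genes. Expression is
reads (or distinct cell-barcode/UMI pairs) per peak, normalized to RPM over
peaks per population. The major isoform of a gene in a population pairs the
maximal-RPM TSS peak with the maximal-RPM TES peak (ties to the 5′-most
end); only this major–major pairing is attempted — establishing one-to-one
TSS–TES matches for genes with several of each is out of scope. Switches
between populations compare major ends with a 100 bp "common end" tolerance
(the original intersection-based procedure states no window); direction is
proximal/distal relative to the gene-body center. Stage dynamics pool cells
per trajectory stage (stages supplied externally; default 6) and report
`log2((count_A + p)/(count_B + p))` with pseudocount p = 1 read, counting
ends within ±50 bp of each alternative coordinate. Differential isoform
expression uses a two-sided Wilcoxon rank-sum test on per-cell RPM with
Benjamini–Hochberg correction — a deliberate, documented replacement for
negative-binomial count modeling, adequate for rank-level calls at this
scale.

## Synthetic data: what it emulates

The generator writes a random-GC toy chromosome (default 500 kb) with 100
non-overlapping genes of 1–3 isoforms whose alternative TSSs/TESs are
separated by 300 bp (well beyond the 20 bp cluster gap). Upstream of each
distinct true end it plants realized motifs: a TATA box 28–36 nt upstream
(rate 0.8) with BREu abutting it on the upstream side (rate 0.3), and
`AATAAA` 12–28 nt upstream of each TES (rate 0.9). Gene abundances are
log-normal (σ = 0.8) unless explicit weights are given. Two cell
populations of 200 cells contribute 200 reads per cell per end type; cell
populations occupy consecutive blocks of the six trajectory stages, and
per-gene isoform usage interpolates linearly from the first population's
profile (major isoform 0 at usage 0.85) at stage 1 to the last population's
(major isoform 1) at stage 6, so population-level majors differ while stage
series change gradually.

False ends are planted per read: 3′ reads misprime at planted genomic
A-runs (≥ 8 A) inside gene bodies at rate 0.15 — internal priming, the
dominant artifact; 5′ reads start at planted GGG sites at rate 0.05
(template switching) or uniformly inside the gene at rate 0.05
(degradation). Internal-priming sites are embedded in an A-rich upstream
neighbourhood (30 nt redrawn at 50 % A): mispriming occurs inside A-rich
stretches in real transcriptomes, and this is precisely what makes
PAS-like hexamers match near such sites by chance, so downstream A-content
— not motif absence — is what resolves them. All reads, true and
artifactual, receive the same Gaussian positional jitter (σ = 2 bp), and
PCR duplicates replicate whole reads including their (barcode, UMI) pair at
rate 0.1. Every read carries exactly one origin label; reference end BEDs
of any completeness can be derived from the truth, and the annotation can
be degraded (dropping ends) to create known "novel" ends.

What the benchmark does **not** emulate: sequencing errors and base
qualities, splicing and exon structure, chance co-location of genes on
opposite strands, mappability artifacts, doublets/ambient RNA, and the
scale of real libraries (millions of reads; the paper-scale TPM threshold
of 3 is far more permissive at toy library sizes, which is why the raw TSS
peak set is artifact-dominated here). Passing tests therefore demonstrate
internal consistency and parameter recovery under the planted model, not
performance on real sequencing data.

## Problem sizes and numerics

Default benchmark sizes (100 genes / 400 cells / 160k reads per end type,
oracle checks on 1,000 random tracks and 10,000 random 60-mers) complete in
a few minutes on one CPU. Degenerate inputs are defined: empty read sets
and empty tracks yield empty outputs; zero library sizes yield zero TPM
with a warning; single-class label sets refuse to train; unsorted tracks
and alignment files, duplicate peak ids, missing contigs and mismatched
feature contracts are hard errors. Quantile normalization uses
right-sided search so re-application is bit-stable; dominant-position and
major-isoform ties resolve 5′-most; the BH step-up uses statsmodels.
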