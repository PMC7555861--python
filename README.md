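# rcatseq

Transcript-end identification and isoform analysis for 5′/3′ end-tag
RNA-seq, in bulk and single cells.

Short-read libraries that tag transcript ends — a template-switching-oligo
(TSO) tag marking the 5′ cap side and an oligo-dT–primed tag marking the 3′
poly-A side — can demarcate the boundaries of RNA isoforms: the transcription
start site (TSS) and transcription end site (TES) of each molecule. The
catch is that raw end signal is contaminated by well-known artifacts: RNA
degradation creates spurious internal 5′ ends, the oligo-dT primer misprimes
at genomic A-rich stretches inside transcripts (internal priming, producing
false TESs), and the TSO occasionally template-switches at internal G-rich
sites (false TSSs). `rcatseq` implements the full computational pipeline for
this kind of data:

1. **Read-end processing** — select reads carrying the TSO tag
   (`GTGGTATCAACGCAGAGTACATGGG`), trim the TSO, select read pairs with a 3′
   tag on R1 and ≥ 10 trailing A on R2, parse UMI and 16 nt cell barcode,
   and convert alignments into strand-aware single-base end positions.
2. **Peak calling** — distance-based clustering of per-position end counts
   (threshold 3 TPM in ≥ 1 sample, 20 bp maximum gap, singletons kept), each
   peak represented by its *dominant position*, the base with maximal pooled
   signal.
3. **Feature engineering** — three named feature groups per peak:
   read-distribution summaries; positional true-end motif blocks (BREu
   `SSRCGCC`, TATA-box `TATAWAWR`, BREd `RTDKKKK` × 50 upstream offsets
   = 150 columns for TSSs, allowing ≤ 2 mismatches; 13 polyadenylation-signal
   hexamers × 50 offsets = 650 columns for TESs, exact match); and artifact
   evidence (downstream A-content for internal priming, G/GGG context for
   template switching). All features are min-max/quantile normalized to
   [0, 1].
4. **End classification** — peaks are labeled TRUE/FALSE against reference
   end catalogs (FANTOM5/PolyA_DB3 surrogates, or synthetic truth), and
   LR/RF/SVM/KNN classifiers are trained with a fixed protocol: stratified
   70/30 split, five-fold cross-validation, two-round (coarse → fine) grid
   search. Performance is accuracy, Acc = (TP+TN)/(TP+TN+FP+FN). Feature
   groups can be ablated one at a time, and a trained model filters peak
   sets.
5. **Isoform analysis** — filtered peaks are assigned to genes (± 2 kb
   rule), quantified as reads-per-million (RPM) or distinct-UMI counts per
   cell population, and each gene's *major isoform* is the pairing of its
   highest-RPM TSS peak with its highest-RPM TES peak. Differences between
   populations yield TSS/TES switch calls (with proximal/distal direction),
   and pooling cells by trajectory stage yields six-stage log2 ratio series
   of alternative end usage.
6. **Synthetic data** — a seeded generator plants genes, isoforms, promoter
   and poly-A motifs, artifact sites, cell populations and trajectory stages
   with full ground truth, so every stage of the pipeline can be scored by
   parameter recovery.

## Worked example

```python
from rcatseq.pipeline import run_end_benchmark

bench = run_end_benchmark(seed=1)
r = bench.tss
print(f"TSS peaks {len(r.peaks)}, RF accuracy {r.rf_test_accuracy:.3f}")
print(f"precision {100*r.precision_unfiltered:.1f}% -> "
      f"{100*r.precision_filtered:.1f}% after filtering")
print(f"end recovery within 10 bp: {100*r.recovery_within_10bp:.1f}%")
print(f"switches: {100*bench.switch_sensitivity:.1f}% sensitivity, "
      f"{bench.switch_false_positives} false positives")
```

prints (seed 1):

```
TSS peaks 2552, RF accuracy 0.978
precision 7.5% -> 100.0% after filtering
end recovery within 10 bp: 95.7%
switches: 98.5% sensitivity, 0 false positives
```

Read it as: on the default synthetic dataset (100 genes, two populations of
200 cells, 200 reads per cell per end type) the raw TSS peak set is dominated
by degradation and template-switch artifacts — only 7.5 % of the 2,552 peaks
sit at a true start site. The random-forest filter removes essentially all of
them while keeping the authentic ends, so 95.7 % of planted TSSs are still
recovered within 10 bp, and downstream major-isoform comparison between the
two populations finds 98.5 % of the planted TSS/TES switches with no false
calls on single-isoform genes.

A command-line interface mirrors the library
(`rcat simulate | ends | peaks | features | train | filter | isoforms |
switches | dynamics`); each subcommand is a thin wrapper over the functions
above.

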