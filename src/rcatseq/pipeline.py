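"""End-to-end benchmark runs on synthetic data with ground-truth scoring.

These functions wire the whole pipeline together — simulate, build count
tracks, call peaks, featurize, train the random-forest end classifier,
filter, and analyse isoforms — and score every stage against the planted
truth.  They back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .annotation import GeneModel, degrade_annotation
from .classify import (
    LabeledPeakSet,
    TrainingProtocol,
    ablate_groups,
    build_labeled_set,
    filter_peaks,
    train,
)
from .features import assemble_features
from .io import GenomeSource
from .isoforms import (
    Novelty,
    assign_peaks,
    call_major_isoforms,
    classify_novelty,
    detect_switches,
    quantify,
    stage_ratios,
)
from .peaks import EndCountTrack, PeakCallingParams, TagCluster, call_peaks
from .read_ends import EndType
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    make_reference_end_beds,
    simulate_end_reads,
    simulate_genome_and_genes,
)


@dataclass
class EndTypeResult:
    """Scored pipeline results for one end type."""

    end_type: EndType
    peaks: list[TagCluster]
    retained: list[TagCluster]
    labeled: LabeledPeakSet
    rf_test_accuracy: float
    precision_unfiltered: float
    precision_filtered: float
    recovery_within_10bp: float
    n_true_ends: int
    ablation_drops: dict[str, float] | None = None


@dataclass
class BenchmarkResult:
    config: SimulationConfig
    genes: list[GeneModel]
    truth: SyntheticTruth
    ends: pd.DataFrame
    tss: EndTypeResult
    tes: EndTypeResult
    novelty_sensitivity: float
    n_novel_truth_peaks: int
    switch_table: pd.DataFrame
    switch_sensitivity: float
    switch_false_positives: int
    n_planted_switch_genes: int


def _true_end_distances(peaks: list[TagCluster], true_ends: pd.DataFrame) -> np.ndarray:
    """Distance from each peak's dominant position to the nearest same-strand
    planted true end (inf when no end exists on that chrom/strand)."""
    by_key = {
        key: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for key, sub in true_ends.groupby(["chrom", "strand"])
    }
    out = np.full(len(peaks), np.inf)
    for i, p in enumerate(peaks):
        sites = by_key.get((p.chrom, p.strand))
        if sites is None or sites.size == 0:
            continue
        j = np.searchsorted(sites, p.dominant_pos)
        out[i] = min(
            abs(int(sites[k]) - p.dominant_pos) for k in (j - 1, j) if 0 <= k < sites.size
        )
    return out


def _recovery(true_ends: pd.DataFrame, peaks: list[TagCluster], tol: int) -> float:
    """Fraction of planted true ends with a retained peak within ``tol`` bp."""
    if len(true_ends) == 0:
        return float("nan")
    doms: dict[tuple[str, str], list[int]] = {}
    for p in peaks:
        doms.setdefault((p.chrom, p.strand), []).append(p.dominant_pos)
    doms = {k: np.sort(np.array(v, dtype=np.int64)) for k, v in doms.items()}
    hit = 0
    for _, row in true_ends.iterrows():
        sites = doms.get((row["chrom"], row["strand"]))
        if sites is None or sites.size == 0:
            continue
        j = np.searchsorted(sites, row["pos"])
        d = min(
            abs(int(sites[k]) - row["pos"]) for k in (j - 1, j) if 0 <= k < sites.size
        )
        hit += d <= tol
    return hit / len(true_ends)


def run_end_benchmark(
    config: SimulationConfig | None = None,
    seed: int = 0,
    label_tolerance: int = 50,
    recovery_tolerance: int = 10,
    novelty_completeness: float = 0.7,
    novelty_tolerance: int = 50,
    switch_tolerance: int = 100,
    params: PeakCallingParams | None = None,
    ablate: tuple[str, ...] = ("TES_3p",),
) -> BenchmarkResult:
    """Full synthetic benchmark: simulate, call, classify, filter, analyse.

    The random-forest classifier is trained per end type on peaks labeled
    TRUE/FALSE against the complete set of planted true ends (tolerance
    ``label_tolerance``); feature-group ablation runs for the end types in
    ``ablate``.  Downstream scoring covers end recovery, novelty detection
    against a ``novelty_completeness``-degraded annotation, and major-isoform
    switch detection between the first and last populations.
    """
    config = replace(config or SimulationConfig(), seed=seed)
    params = params or PeakCallingParams()
    protocol = TrainingProtocol(seed=seed, algorithms=("RF",))
    genome_dict, genes, truth = simulate_genome_and_genes(config)
    genome = GenomeSource(genome_dict)
    ends, truth = simulate_end_reads(config, genes, truth)

    results: dict[EndType, EndTypeResult] = {}
    for end_type in (EndType.TSS_5p, EndType.TES_3p):
        sub = ends[ends["end_type"] == end_type.value]
        track = EndCountTrack.from_ends(sub)
        peaks = call_peaks(track, params, end_type)
        feats = assemble_features(peaks, genome, end_type, genes=genes)
        true_ends = truth.true_ends(end_type)
        ref_bed = pd.DataFrame(
            {
                "chrom": true_ends["chrom"],
                "start": true_ends["pos"],
                "end": true_ends["pos"] + 1,
                "name": true_ends["gene_id"],
                "score": 0,
                "strand": true_ends["strand"],
            }
        )
        labeled = build_labeled_set(feats, peaks, ref_bed, tolerance=label_tolerance)
        rf = train(labeled, protocol, algorithms=("RF",))["RF"]
        retained, _table = filter_peaks(rf, peaks, feats)

        labels = labeled.labels
        prec_unf = float(labels.mean()) if len(labels) else float("nan")
        ret_ids = [p.peak_id for p in retained]
        prec_fil = float(labels.loc[ret_ids].mean()) if ret_ids else 0.0
        recov = _recovery(true_ends, retained, recovery_tolerance)
        drops = None
        if end_type.value in ablate:
            drops = ablate_groups(labeled, protocol, algorithm="RF")
        results[end_type] = EndTypeResult(
            end_type=end_type,
            peaks=peaks,
            retained=retained,
            labeled=labeled,
            rf_test_accuracy=rf.metrics.acc,
            precision_unfiltered=prec_unf,
            precision_filtered=prec_fil,
            recovery_within_10bp=recov,
            n_true_ends=len(true_ends),
            ablation_drops=drops,
        )

    # novelty against a deliberately incomplete annotation
    degraded, dropped = degrade_annotation(genes, novelty_completeness, seed=seed)
    all_retained = results[EndType.TSS_5p].retained + results[EndType.TES_3p].retained
    assignments = assign_peaks(all_retained, degraded)
    novelty = classify_novelty(assignments, all_retained, degraded, tolerance=novelty_tolerance)
    dropped_sites = {
        (g.chrom, g.strand, et, pos)
        for g in genes
        for (et, pos) in dropped.get(g.gene_id, ())
    }
    n_novel_truth, n_flagged = 0, 0
    for p in all_retained:
        near_dropped = any(
            key[:2] == (p.chrom, p.strand)
            and key[2] == EndType(p.end_type).value
            and abs(key[3] - p.dominant_pos) <= recovery_tolerance
            for key in dropped_sites
        )
        if near_dropped:
            n_novel_truth += 1
            if novelty[p.peak_id] is not Novelty.known_end:
                n_flagged += 1
    novelty_sensitivity = n_flagged / n_novel_truth if n_novel_truth else float("nan")

    # major-isoform switches between the first and last population
    full_assign = assign_peaks(all_retained, genes)
    expr, _unassigned = quantify(all_retained, ends)
    pop_a, pop_b = "pop0", f"pop{config.n_populations - 1}"
    calls_a = call_major_isoforms(expr, full_assign, all_retained, pop_a)
    calls_b = call_major_isoforms(expr, full_assign, all_retained, pop_b)
    switches = detect_switches(calls_a, calls_b, genes, same_end_tolerance=switch_tolerance)
    planted = _planted_switches(truth, config, switch_tolerance)
    detected = dict(zip(switches["gene_id"], switches["category"]))
    n_hit = sum(
        1 for gid, cat in planted.items() if detected.get(gid) == cat
    )
    single_iso = set(
        truth.isoforms.groupby("gene_id")
        .size()
        .loc[lambda s: s == 1]
        .index
    )
    fp = int(
        sum(1 for gid, cat in detected.items() if gid in single_iso and cat != "none")
    )
    return BenchmarkResult(
        config=config,
        genes=genes,
        truth=truth,
        ends=ends,
        tss=results[EndType.TSS_5p],
        tes=results[EndType.TES_3p],
        novelty_sensitivity=novelty_sensitivity,
        n_novel_truth_peaks=n_novel_truth,
        switch_table=switches,
        switch_sensitivity=n_hit / len(planted) if planted else float("nan"),
        switch_false_positives=fp,
        n_planted_switch_genes=len(planted),
    )


def _planted_switches(
    truth: SyntheticTruth, config: SimulationConfig, tolerance: int
) -> dict[str, str]:
    """Expected switch category per multi-isoform gene: the first population's
    major isoform is isoform 0, the last population's isoform 1."""
    planted = {}
    for gid, sub in truth.isoforms.groupby("gene_id"):
        if len(sub) < 2:
            continue
        a = sub[sub["isoform"] == 0].iloc[0]
        b = sub[sub["isoform"] == (config.n_populations - 1) % len(sub)].iloc[0]
        tss_moved = abs(int(a["tss"]) - int(b["tss"])) > tolerance
        tes_moved = abs(int(a["tes"]) - int(b["tes"])) > tolerance
        if tss_moved and tes_moved:
            planted[gid] = "both"
        elif tss_moved:
            planted[gid] = "TSS_switch"
        elif tes_moved:
            planted[gid] = "TES_switch"
    return planted


def run_quantification_benchmark(
    seed: int = 0,
    n_transcripts: int = 92,
    decades: float = 4.0,
    cells: int = 20,
    reads_per_cell: int = 500,
) -> dict:
    """Spike-in-style quantification check.

    Simulates single-isoform transcripts with known abundances spanning
    ``decades`` orders of magnitude (an ERCC-mix analogue), runs peak calling
    and RPM quantification, and correlates measured RPM per transcript with
    the known input abundance.
    """
    weights = tuple(np.logspace(0.0, decades, n_transcripts))
    config = SimulationConfig(
        seed=seed,
        n_genes=n_transcripts,
        isoform_range=(1, 1),
        n_populations=1,
        cells_per_population=cells,
        reads_per_cell=reads_per_cell,
        gene_weights=weights,
    )
    genome_dict, genes, truth = simulate_genome_and_genes(config)
    ends, truth = simulate_end_reads(config, genes, truth)
    out = {}
    for end_type in (EndType.TSS_5p, EndType.TES_3p):
        sub = ends[ends["end_type"] == end_type.value]
        track = EndCountTrack.from_ends(sub)
        peaks = call_peaks(track, end_type=end_type)
        assignments = assign_peaks(peaks, genes)
        expr, _ = quantify(peaks, sub)
        gene_of = {a.peak_id: a.gene_id for a in assignments}
        expr = expr.assign(gene_id=expr["peak_id"].map(gene_of))
        per_gene = (
            expr.dropna(subset=["gene_id"]).groupby("gene_id")["rpm"].sum()
        )
        measured = per_gene.reindex(truth.gene_weights.index, fill_value=0.0)
        r = float(sstats.pearsonr(measured.to_numpy(), truth.gene_weights.to_numpy())[0])
        key = "tss" if end_type is EndType.TSS_5p else "tes"
        out[f"pearson_{key}"] = r
    out["n_transcripts"] = n_transcripts
    return out


def run_stage_benchmark(
    seed: int = 0,
    n_genes: int = 10,
    window: int = 50,
) -> dict:
    """Trajectory-stage dynamics check.

    All genes carry two isoforms with alternative TSSs; isoform usage
    interpolates linearly from the progenitor population's profile at stage 1
    to the differentiated population's at stage 6.  The fitted per-stage
    log2 ratios of the two alternative ends should fall monotonically.
    """
    config = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        genome_length=max(500_000 // 100 * n_genes, 5000 * n_genes),
        isoform_range=(2, 2),
        switch_types=("tss",),
    )
    genome_dict, genes, truth = simulate_genome_and_genes(config)
    ends, truth = simulate_end_reads(config, genes, truth)
    stage_of = dict(zip(truth.cells["cell_barcode"], truth.cells["stage"]))
    series = []
    for gid, sub in truth.isoforms.groupby("gene_id"):
        a = int(sub[sub["isoform"] == 0].iloc[0]["tss"])
        b = int(sub[sub["isoform"] == 1].iloc[0]["tss"])
        s = stage_ratios(
            ends,
            stage_of,
            chrom=config.chrom,
            strand=sub.iloc[0]["strand"],
            end_type=EndType.TSS_5p,
            pos_a=a,
            pos_b=b,
            gene_id=gid,
            n_stages=config.n_stages,
            window=window,
        )
        series.append(s)
    n_monotone = sum(
        1 for s in series if all(x > y for x, y in zip(s.ratios, s.ratios[1:]))
    )
    return {
        "series": series,
        "monotone_fraction": n_monotone / len(series),
        "n_genes": len(series),
    }
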