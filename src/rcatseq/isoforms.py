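"""Gene assignment, end quantification, and isoform-switch analysis.

Filtered peaks are assigned to genes using the +-2 kb rule (a peak belongs to
a gene when its dominant position lies between 2 kb upstream of the
annotated TSSs and 2 kb downstream of the annotated TESs, on the gene's
strand), quantified as reads-per-million (RPM) or distinct-UMI counts per
cell population, and matched into major isoforms: per gene and population,
the maximal-RPM TSS peak paired with the maximal-RPM TES peak.  Differences
in major ends between populations yield TSS/TES switch calls; pooling cells
by trajectory stage yields log-ratio series of alternative end usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel
from .peaks import TagCluster
from .read_ends import EndType


class Novelty(str, Enum):
    known_end = "known_end"
    novel_end_known_gene = "novel_end_known_gene"
    novel_gene = "novel_gene"


@dataclass(frozen=True)
class PeakAssignment:
    peak_id: str
    gene_id: str | None
    distance_to_nearest_end: int | None = None


@dataclass(frozen=True)
class IsoformCall:
    """A population's major isoform for one gene: its highest-RPM TSS peak
    matched with its highest-RPM TES peak."""

    gene_id: str
    population: str
    major_tss: int
    major_tes: int
    tss_peak_id: str
    tes_peak_id: str
    tss_rpm: float
    tes_rpm: float


@dataclass(frozen=True)
class StageRatioSeries:
    """Per-stage log2 usage ratio of two alternative ends of one gene."""

    gene_id: str
    end_type: EndType
    pos_a: int
    pos_b: int
    ratios: tuple[float, ...]
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]


def _nearest_distance(sites: Sequence[int], pos: int) -> int | None:
    if not sites:
        return None
    arr = np.sort(np.asarray(sites, dtype=np.int64))
    i = np.searchsorted(arr, pos)
    return min(
        abs(int(arr[j]) - pos) for j in (i - 1, i) if 0 <= j < arr.size
    )


def _annotated_sites(gene: GeneModel, end_type: EndType) -> tuple[int, ...]:
    return gene.tss_sites if end_type is EndType.TSS_5p else gene.tes_sites


def assign_peaks(
    peaks: Sequence[TagCluster],
    genes: Sequence[GeneModel],
    margin: int = 2000,
) -> list[PeakAssignment]:
    """Assign each peak to a gene by the +-``margin`` rule.

    A peak belongs to gene g when its dominant position lies within
    ``[span_start - margin, span_end + margin)`` on g's strand (the span
    covers all annotated ends, so the margin extends 2 kb upstream of the
    TSSs and 2 kb downstream of the TESs in transcript orientation).  When
    several gene windows overlap a peak, the gene with the nearest annotated
    end of the peak's end type wins.  Unassigned peaks are novel-gene
    candidates.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    out = []
    for p in peaks:
        best: tuple[int, str] | None = None
        for g in by_key.get((p.chrom, p.strand), ()):
            s, e = g.span
            if s - margin <= p.dominant_pos < e + margin:
                sites = _annotated_sites(g, EndType(p.end_type)) or (
                    g.tss_sites + g.tes_sites
                )
                d = _nearest_distance(sites, p.dominant_pos)
                if best is None or d < best[0]:
                    best = (d, g.gene_id)
        out.append(
            PeakAssignment(
                peak_id=p.peak_id,
                gene_id=None if best is None else best[1],
                distance_to_nearest_end=None if best is None else best[0],
            )
        )
    return out


def classify_novelty(
    assignments: Sequence[PeakAssignment],
    peaks: Sequence[TagCluster],
    genes: Sequence[GeneModel],
    tolerance: int = 50,
) -> dict[str, Novelty]:
    """Label each peak against the annotation.

    known_end: within ``tolerance`` of an annotated same-type end of the
    assigned gene; novel_end_known_gene: assigned but distant from every
    annotated end of its type; novel_gene: not inside any gene window.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    peak_by_id = {p.peak_id: p for p in peaks}
    out = {}
    for a in assignments:
        if a.gene_id is None:
            out[a.peak_id] = Novelty.novel_gene
            continue
        p = peak_by_id[a.peak_id]
        sites = _annotated_sites(gene_by_id[a.gene_id], EndType(p.end_type))
        d = _nearest_distance(sites, p.dominant_pos)
        out[a.peak_id] = (
            Novelty.known_end
            if d is not None and d <= tolerance
            else Novelty.novel_end_known_gene
        )
    return out


def quantify(
    peaks: Sequence[TagCluster],
    ends: pd.DataFrame,
    mode: str = "reads",
    population_col: str = "sample_id",
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression of each peak per cell population.

    Reads mode counts ends whose position falls within the peak span; UMI
    mode counts distinct (cell barcode, UMI) pairs per peak instead, so PCR
    duplicates collapse.  RPM normalizes each population's counts over peaks
    to one million.  Returns a long table (peak_id, population, count, rpm)
    and the per-population count of ends falling in no peak (conservation:
    assigned + unassigned = total ends per population).
    """
    if mode not in ("reads", "umi"):
        raise ValueError("mode must be 'reads' or 'umi'")
    spans: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, group in _group_peaks(peaks).items():
        group.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in group], dtype=np.int64)
        stops = np.array([p.end for p in group], dtype=np.int64)
        ids = np.array([p.peak_id for p in group], dtype=object)
        spans[key] = (starts, stops, ids)

    df = ends.copy()
    peak_col = np.full(len(df), None, dtype=object)
    for key, (starts, stops, ids) in spans.items():
        chrom, strand, etype = key
        mask = (
            (df["chrom"] == chrom)
            & (df["strand"] == strand)
            & (df["end_type"] == etype)
        ).to_numpy()
        if not mask.any():
            continue
        pos = df.loc[mask, "pos"].to_numpy(dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < stops[np.clip(j, 0, len(stops) - 1)])
        vals = np.full(mask.sum(), None, dtype=object)
        vals[ok] = ids[j[ok]]
        peak_col[mask] = vals
    df["peak_id"] = peak_col

    unassigned = (
        df[df["peak_id"].isna()].groupby(population_col, observed=True).size()
    )
    hit = df[df["peak_id"].notna()]
    if mode == "umi":
        hit = hit.drop_duplicates(subset=[population_col, "cell_barcode", "umi", "peak_id"])
    counts = (
        hit.groupby([population_col, "peak_id"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={population_col: "population"})
    )
    all_ids = [p.peak_id for p in peaks]
    pops = sorted(ends[population_col].dropna().unique())
    full = (
        pd.MultiIndex.from_product([pops, all_ids], names=["population", "peak_id"])
        .to_frame(index=False)
        .merge(counts, how="left", on=["population", "peak_id"])
        .fillna({"count": 0})
    )
    full["count"] = full["count"].astype(int)
    totals = full.groupby("population")["count"].transform("sum")
    full["rpm"] = np.where(totals > 0, full["count"] * 1e6 / totals, 0.0)
    return full, unassigned.reindex(pops, fill_value=0)


def _group_peaks(peaks: Sequence[TagCluster]):
    groups: dict[tuple[str, str, str], list[TagCluster]] = {}
    for p in peaks:
        groups.setdefault((p.chrom, p.strand, EndType(p.end_type).value), []).append(p)
    return groups


def call_major_isoforms(
    expr: pd.DataFrame,
    assignments: Sequence[PeakAssignment],
    peaks: Sequence[TagCluster],
    population: str,
) -> list[IsoformCall]:
    """Match each gene's major TSS with its major TES in one population.

    The major end of each type is the assigned peak with maximal RPM; ties
    break to the 5'-most end in transcript orientation.  Genes lacking an
    expressed peak of either type yield no call.
    """
    gene_of = {a.peak_id: a.gene_id for a in assignments}
    peak_by_id = {p.peak_id: p for p in peaks}
    sub = expr[(expr["population"] == population) & (expr["count"] > 0)]

    best: dict[tuple[str, EndType], tuple[float, TagCluster, float]] = {}
    for _, row in sub.iterrows():
        p = peak_by_id.get(row["peak_id"])
        if p is None:
            continue
        gid = gene_of.get(p.peak_id)
        if gid is None:
            continue
        key = (gid, EndType(p.end_type))
        rpm = float(row["rpm"])
        cur = best.get(key)
        if cur is None or rpm > cur[0] or (
            rpm == cur[0] and _more_5prime(p, cur[1])
        ):
            best[key] = (rpm, p, rpm)
    calls = []
    genes = {gid for gid, _ in best}
    for gid in sorted(genes):
        tss = best.get((gid, EndType.TSS_5p))
        tes = best.get((gid, EndType.TES_3p))
        if tss is None or tes is None:
            continue
        calls.append(
            IsoformCall(
                gene_id=gid,
                population=population,
                major_tss=tss[1].dominant_pos,
                major_tes=tes[1].dominant_pos,
                tss_peak_id=tss[1].peak_id,
                tes_peak_id=tes[1].peak_id,
                tss_rpm=tss[0],
                tes_rpm=tes[0],
            )
        )
    return calls


def _more_5prime(a: TagCluster, b: TagCluster) -> bool:
    return a.dominant_pos < b.dominant_pos if a.strand == "+" else a.dominant_pos > b.dominant_pos


def detect_switches(
    calls_a: Sequence[IsoformCall],
    calls_b: Sequence[IsoformCall],
    genes: Sequence[GeneModel] | None = None,
    same_end_tolerance: int = 100,
) -> pd.DataFrame:
    """Categorize major-isoform differences between two populations.

    Per gene co-called in both: ``TSS_switch`` when the major TESs agree
    within ``same_end_tolerance`` but the major TSSs do not, ``TES_switch``
    for the mirror case, ``both`` or ``none`` otherwise.  When gene models
    are supplied, switched ends are annotated proximal/distal relative to the
    gene body center.
    """
    centers = {g.gene_id: g.center for g in genes} if genes else {}
    a_by_gene = {c.gene_id: c for c in calls_a}
    rows = []
    for cb in calls_b:
        ca = a_by_gene.get(cb.gene_id)
        if ca is None:
            continue
        d_tss = abs(ca.major_tss - cb.major_tss)
        d_tes = abs(ca.major_tes - cb.major_tes)
        tss_moved = d_tss > same_end_tolerance
        tes_moved = d_tes > same_end_tolerance
        if tss_moved and tes_moved:
            cat = "both"
        elif tss_moved:
            cat = "TSS_switch"
        elif tes_moved:
            cat = "TES_switch"
        else:
            cat = "none"

        def direction(pos_a: int, pos_b: int, moved: bool) -> str:
            c = centers.get(cb.gene_id)
            if not moved or c is None:
                return "none"
            return "proximal" if abs(pos_b - c) < abs(pos_a - c) else "distal"

        rows.append(
            {
                "gene_id": cb.gene_id,
                "category": cat,
                "tss_a": ca.major_tss,
                "tss_b": cb.major_tss,
                "tes_a": ca.major_tes,
                "tes_b": cb.major_tes,
                "tss_distance": d_tss,
                "tes_distance": d_tes,
                "tss_direction": direction(ca.major_tss, cb.major_tss, tss_moved),
                "tes_direction": direction(ca.major_tes, cb.major_tes, tes_moved),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "category", "tss_a", "tss_b", "tes_a", "tes_b",
            "tss_distance", "tes_distance", "tss_direction", "tes_direction",
        ],
    )


def stage_ratios(
    ends: pd.DataFrame,
    stage_labels: Mapping[str, int],
    chrom: str,
    strand: str,
    end_type: EndType | str,
    pos_a: int,
    pos_b: int,
    gene_id: str = "",
    n_stages: int = 6,
    window: int = 50,
    pseudocount: float = 1.0,
) -> StageRatioSeries:
    """Log2 usage ratio of two alternative ends across trajectory stages.

    Cells are pooled per stage via ``stage_labels`` (cell barcode -> stage in
    1..n_stages); ends within ``window`` bp of each alternative coordinate
    are counted and the per-stage ratio is
    ``log2((count_a + pseudocount) / (count_b + pseudocount))``.
    """
    end_type = EndType(end_type)
    sub = ends[
        (ends["chrom"] == chrom)
        & (ends["strand"] == strand)
        & (ends["end_type"] == end_type.value)
    ]
    stage = sub["cell_barcode"].map(stage_labels)
    pos = sub["pos"].to_numpy(dtype=np.int64)
    near_a = np.abs(pos - pos_a) <= window
    near_b = np.abs(pos - pos_b) <= window
    ca, cb, ratios = [], [], []
    for s in range(1, n_stages + 1):
        m = (stage == s).to_numpy()
        na, nb = int((near_a & m).sum()), int((near_b & m).sum())
        ca.append(na)
        cb.append(nb)
        ratios.append(float(np.log2((na + pseudocount) / (nb + pseudocount))))
    return StageRatioSeries(
        gene_id=gene_id,
        end_type=end_type,
        pos_a=pos_a,
        pos_b=pos_b,
        ratios=tuple(ratios),
        counts_a=tuple(ca),
        counts_b=tuple(cb),
    )


def compare_isoform_expression(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-isoform fold change and rank test between two cell groups.

    ``expr_a`` / ``expr_b``: isoforms x cells RPM matrices sharing a row
    index.  Returns log2 fold change of mean RPM (with pseudocount),
    two-sided Wilcoxon rank-sum p, and Benjamini-Hochberg q per isoform.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("expression matrices must share an isoform index")
    rows = []
    for iso in expr_a.index:
        x = expr_a.loc[iso].to_numpy(dtype=float)
        y = expr_b.loc[iso].to_numpy(dtype=float)
        lfc = float(np.log2((x.mean() + pseudocount) / (y.mean() + pseudocount)))
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"isoform": iso, "log2_fc": lfc, "pvalue": p})
    out = pd.DataFrame(rows).set_index("isoform")
    if len(out):
        out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        out["qvalue"] = []
    return out
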