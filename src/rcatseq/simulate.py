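"""Seeded synthetic genomes, gene models and end-read datasets with ground truth.

The generator plants what the pipeline is meant to find: gene models with
one to three isoforms whose TSS/TES differ between cell populations,
promoter (TATA/BREu) and polyadenylation-signal motifs upstream of the true
ends, and the sequence contexts that produce false-positive ends — genomic
A-runs inside gene bodies (internal priming of the oligo-dT primer), G-rich
internal sites (spurious template switching), and uniform internal 5' ends
(RNA degradation).  Every simulated read carries exactly one origin label,
every cell a population and trajectory stage, so downstream modules can be
scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .read_ends import EndType

_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "S": "CG", "R": "AG", "W": "AT", "K": "GT", "D": "AGT", "V": "ACG", "N": "ACGT",
}

ORIGINS = ("true_end", "internal_priming", "template_switch", "degradation")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a 500 kb toy chromosome with 100 genes, two cell
    populations of 200 cells each and 200 reads per cell per end type —
    small enough to run in minutes on one CPU while exercising every
    pipeline stage.  Artifact rates are per-read probabilities; internal
    priming is the dominant 3'-end artifact.
    """

    seed: int = 0
    chrom: str = "chrS"
    genome_length: int = 500_000
    gc_content: float = 0.45
    n_genes: int = 100
    isoform_range: tuple[int, int] = (1, 3)
    switch_types: tuple[str, ...] = ("tss", "tes", "both")
    end_separation: int = 300
    tata_rate: float = 0.8
    breu_rate: float = 0.3
    pas_rate: float = 0.9
    n_populations: int = 2
    cells_per_population: int = 200
    reads_per_cell: int = 200
    major_usage: float = 0.85
    internal_priming_rate: float = 0.15
    template_switch_rate: float = 0.05
    degradation_rate: float = 0.05
    # oligo-dT mispriming happens inside genomically A-rich stretches, so the
    # sequence upstream of a planted A-run is itself A-enriched — which is why
    # PAS-like hexamers occur there by chance and downstream A-content is
    # needed to resolve such peaks
    ip_context_a_fraction: float = 0.5
    ip_context_len: int = 30
    jitter_sd: float = 2.0
    pcr_duplication_rate: float = 0.1
    n_stages: int = 6
    stage_interpolation: bool = True
    abundance_sigma: float = 0.8
    gene_weights: tuple[float, ...] | None = None
    umi_len: int = 8
    barcode_len: int = 16

    def __post_init__(self):
        for name in (
            "tata_rate", "breu_rate", "pas_rate", "major_usage",
            "internal_priming_rate", "template_switch_rate",
            "degradation_rate", "pcr_duplication_rate", "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.internal_priming_rate > 1 or self.template_switch_rate + self.degradation_rate > 1:
            raise ValueError("artifact rates must sum to at most 1 per end type")
        lo, hi = self.isoform_range
        if not 1 <= lo <= hi:
            raise ValueError("isoform_range must satisfy 1 <= lo <= hi")
        if self.genome_length // self.n_genes < 3000:
            raise ValueError("genome too short for the requested gene count")
        if self.gene_weights is not None and len(self.gene_weights) != self.n_genes:
            raise ValueError("gene_weights length must equal n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run.

    ``isoforms``: one row per gene isoform with its true TSS/TES;
    ``artifact_sites``: planted false-end sites with their kind;
    ``interiors``: per-gene genomic interval for internal (degradation) ends;
    ``gene_weights``: relative transcript abundance per gene;
    ``cells`` and ``read_origins`` are filled by ``simulate_end_reads``.
    """

    isoforms: pd.DataFrame
    artifact_sites: pd.DataFrame
    interiors: dict[str, tuple[int, int]]
    gene_weights: pd.Series
    cells: pd.DataFrame | None = None
    read_origins: pd.DataFrame | None = None

    def true_ends(self, end_type: EndType | str) -> pd.DataFrame:
        """Distinct planted ends of one type: columns chrom, pos, strand, gene_id."""
        col = "tss" if EndType(end_type) is EndType.TSS_5p else "tes"
        df = self.isoforms[["gene_id", "chrom", "strand", col]].rename(columns={col: "pos"})
        return df.drop_duplicates(subset=["chrom", "strand", "pos"]).reset_index(drop=True)

    def usage_matrix(self, gene_id: str, n_stages: int, n_populations: int,
                     major_usage: float, interpolate: bool) -> np.ndarray:
        """Per-stage isoform usage (n_stages x n_isoforms) for one gene.

        Population p's major isoform is isoform ``p % n_isoforms``; with
        stage interpolation, usage moves linearly from the first population's
        profile (stage 1) to the last population's (stage n_stages).
        """
        n_iso = int((self.isoforms["gene_id"] == gene_id).sum())
        first = _usage_vector(n_iso, 0 % n_iso, major_usage)
        last = _usage_vector(n_iso, (n_populations - 1) % n_iso, major_usage)
        out = np.empty((n_stages, n_iso))
        for s in range(n_stages):
            if interpolate and n_stages > 1:
                t = s / (n_stages - 1)
                out[s] = (1 - t) * first + t * last
            else:
                # stages partition into consecutive per-population blocks
                p = min(s * n_populations // n_stages, n_populations - 1)
                out[s] = _usage_vector(n_iso, p % n_iso, major_usage)
        return out


def _usage_vector(n_iso: int, major_idx: int, major_usage: float) -> np.ndarray:
    if n_iso == 1:
        return np.array([1.0])
    u = np.full(n_iso, (1.0 - major_usage) / (n_iso - 1))
    u[major_idx] = major_usage
    return u


def _realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_IUPAC_CHOICES[c])) for c in pattern)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_motif(seq: np.ndarray, strand: str, end_pos: int, offset: int, motif: str) -> None:
    """Plant ``motif`` so its 5'-most base sits ``offset`` nt upstream of
    ``end_pos`` in transcript orientation."""
    m = len(motif)
    if strand == "+":
        start = end_pos - offset
        seq[start : start + m] = list(motif)
    else:
        start = end_pos + offset - m + 1
        seq[start : start + m] = [_COMP[c] for c in reversed(motif)]


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Deterministic toy genome with planted genes, motifs and artifact sites."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=config.genome_length, p=p)

    slot = config.genome_length // config.n_genes
    sep = config.end_separation
    lo_iso, hi_iso = config.isoform_range
    genes: list[GeneModel] = []
    iso_rows, art_rows = [], []
    interiors: dict[str, tuple[int, int]] = {}

    for g in range(config.n_genes):
        gid = f"g{g:04d}"
        margin = 300
        start = slot * g + margin + int(rng.integers(0, 400))
        max_len = slot * (g + 1) - margin - start
        length = int(rng.integers(1800, min(3600, max_len) + 1))
        end = start + length
        strand = str(rng.choice(["+", "-"]))
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        switch = str(rng.choice(list(config.switch_types))) if n_iso > 1 else "none"

        five = start if strand == "+" else end - 1
        three = end - 1 if strand == "+" else start
        inward = 1 if strand == "+" else -1
        tss_list, tes_list = [], []
        for k in range(n_iso):
            tss = five + inward * k * sep if switch in ("tss", "both") else five
            tes = three - inward * k * sep if switch in ("tes", "both") else three
            tss_list.append(tss)
            tes_list.append(tes)
            iso_rows.append(
                {"gene_id": gid, "isoform": k, "chrom": config.chrom,
                 "strand": strand, "tss": tss, "tes": tes, "switch_type": switch}
            )

        all_ends = sorted(set(tss_list) | set(tes_list))
        interior = (min(all_ends) + 150, max(all_ends) - 150)
        interiors[gid] = interior

        # plant true-end motifs upstream of each distinct end
        for tss in dict.fromkeys(tss_list):
            tata_off = None
            if rng.random() < config.tata_rate:
                tata_off = int(rng.integers(28, 37))
                _write_motif(seq, strand, tss, tata_off, _realize_iupac("TATAWAWR", rng))
            if rng.random() < config.breu_rate:
                # BREu abuts the TATA box on its upstream side
                # start offsets: a 7-mer starting at k covers k .. k-6, so
                # k >= tata_off + 7 keeps BREu clear of the TATA box
                base = tata_off if tata_off is not None else int(rng.integers(28, 37))
                breu_off = base + 7 + int(rng.integers(0, 3))
                _write_motif(seq, strand, tss, breu_off, _realize_iupac("SSRCGCC", rng))
        for tes in dict.fromkeys(tes_list):
            if rng.random() < config.pas_rate:
                _write_motif(seq, strand, tes, int(rng.integers(12, 29)), "AATAAA")

        # plant artifact sites in the gene interior, away from true ends
        placed: list[int] = []

        def pick_site(room: int) -> int | None:
            lo, hi = interior
            if hi - lo < 2 * room + 10:
                return None
            for _ in range(100):
                cand = int(rng.integers(lo + room, hi - room))
                if all(abs(cand - e) >= 100 for e in all_ends) and all(
                    abs(cand - q) >= 40 for q in placed
                ):
                    return cand
            return None

        for _ in range(2):  # internal-priming sites: A-run >= 8 downstream
            site = pick_site(room=20)
            if site is None:
                continue
            run = int(rng.integers(8, 13))
            ctx = config.ip_context_len
            a_frac = config.ip_context_a_fraction
            rest = (1 - a_frac) / 3
            if strand == "+":
                seq[site + 1 : site + 1 + run] = "A"
                lo = max(0, site - ctx)
                seq[lo : site + 1] = rng.choice(
                    _BASES, size=site + 1 - lo, p=[a_frac, rest, rest, rest]
                )
            else:
                seq[site - run : site] = "T"
                hi = min(len(seq), site + ctx)
                seq[site:hi] = rng.choice(
                    _BASES, size=hi - site, p=[rest, rest, rest, a_frac]
                )
            placed.append(site)
            art_rows.append(
                {"gene_id": gid, "kind": "internal_priming",
                 "end_type": EndType.TES_3p.value, "chrom": config.chrom,
                 "strand": strand, "pos": site}
            )
        for _ in range(2):  # template-switch sites: GGG at the false start
            site = pick_site(room=5)
            if site is None:
                continue
            if strand == "+":
                seq[site : site + 3] = "G"
            else:
                seq[site - 2 : site + 1] = "C"
            placed.append(site)
            art_rows.append(
                {"gene_id": gid, "kind": "template_switch",
                 "end_type": EndType.TSS_5p.value, "chrom": config.chrom,
                 "strand": strand, "pos": site}
            )

        genes.append(
            GeneModel(
                gene_id=gid, chrom=config.chrom, strand=strand,
                tss_sites=tuple(dict.fromkeys(tss_list)),
                tes_sites=tuple(dict.fromkeys(tes_list)),
            )
        )

    if config.gene_weights is not None:
        weights = np.asarray(config.gene_weights, dtype=float)
    else:
        weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_genes)
    truth = SyntheticTruth(
        isoforms=pd.DataFrame(iso_rows),
        artifact_sites=pd.DataFrame(
            art_rows, columns=["gene_id", "kind", "end_type", "chrom", "strand", "pos"]
        ),
        interiors=interiors,
        gene_weights=pd.Series(weights, index=[g.gene_id for g in genes], name="weight"),
    )
    genome = {config.chrom: "".join(seq)}
    return genome, genes, truth


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    arr = rng.integers(0, 4, size=(n, k))
    return ["".join(row) for row in _BASES[arr]]


def _unique_barcodes(rng: np.random.Generator, n: int, k: int) -> list[str]:
    codes = _random_kmers(rng, n, k)
    seen = set()
    for i, c in enumerate(codes):
        while c in seen:
            c = "".join(_BASES[rng.integers(0, 4, size=k)])
        codes[i] = c
        seen.add(c)
    return codes


def simulate_end_reads(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate mapped end reads for every cell and both end types.

    True-end reads are jittered around the planted isoform ends; artifact
    reads are placed at the planted internal-priming (3') and
    template-switch (5') sites or uniformly inside the gene (degradation,
    5' only).  PCR duplicates replicate whole reads including their
    (barcode, UMI) pair.  Fills ``truth.cells`` and ``truth.read_origins``
    and returns the mapped-ends table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_pop = config.n_populations
    n_cells = config.cells_per_population
    total_cells = n_pop * n_cells
    barcodes = _unique_barcodes(rng, total_cells, config.barcode_len)
    pops = np.repeat(np.arange(n_pop), n_cells)
    # populations occupy consecutive stage blocks along the trajectory
    stage_edges = np.linspace(0, config.n_stages, n_pop + 1)
    stages = np.empty(total_cells, dtype=int)
    for p in range(n_pop):
        lo, hi = int(stage_edges[p]), int(stage_edges[p + 1])
        hi = max(hi, lo + 1)
        stages[pops == p] = rng.integers(lo + 1, hi + 1, size=(pops == p).sum())
    cells = pd.DataFrame(
        {"cell_barcode": barcodes,
         "population": [f"pop{p}" for p in pops],
         "stage": stages}
    )

    gene_ids = [g.gene_id for g in genes]
    strand_of = {g.gene_id: g.strand for g in genes}
    w = truth.gene_weights.reindex(gene_ids).to_numpy(dtype=float)
    w = w / w.sum()
    iso = truth.isoforms
    iso_ends = {
        gid: (sub["tss"].to_numpy(), sub["tes"].to_numpy())
        for gid, sub in iso.groupby("gene_id")
    }
    usage_by_gene = {
        gid: truth.usage_matrix(
            gid, config.n_stages, n_pop, config.major_usage, config.stage_interpolation
        )
        for gid in gene_ids
    }
    art = truth.artifact_sites
    ip_sites = {g: s["pos"].to_numpy() for g, s in art[art["kind"] == "internal_priming"].groupby("gene_id")}
    ts_sites = {g: s["pos"].to_numpy() for g, s in art[art["kind"] == "template_switch"].groupby("gene_id")}

    frames, origin_frames = [], []
    for end_type in (EndType.TSS_5p, EndType.TES_3p):
        n = total_cells * config.reads_per_cell
        cell_idx = np.repeat(np.arange(total_cells), config.reads_per_cell)
        gene_idx = rng.choice(len(gene_ids), size=n, p=w)
        pos = np.zeros(n, dtype=np.int64)
        origin = np.empty(n, dtype=object)
        iso_of_read = np.full(n, -1, dtype=int)
        u_origin = rng.random(n)
        u_iso = rng.random(n)
        for gi, gid in enumerate(gene_ids):
            sel = np.flatnonzero(gene_idx == gi)
            if sel.size == 0:
                continue
            U = usage_by_gene[gid]
            cum = np.cumsum(U, axis=1)
            st = stages[cell_idx[sel]] - 1
            k = (u_iso[sel][:, None] > cum[st]).sum(axis=1)
            iso_of_read[sel] = k
            tss_arr, tes_arr = iso_ends[gid]
            true_pos = tss_arr[k] if end_type is EndType.TSS_5p else tes_arr[k]
            jit = np.rint(rng.normal(0.0, config.jitter_sd, size=sel.size)).astype(np.int64)
            pos[sel] = true_pos + jit
            origin[sel] = "true_end"
            uo = u_origin[sel]
            if end_type is EndType.TSS_5p:
                ts_mask = uo < config.template_switch_rate
                deg_mask = (~ts_mask) & (
                    uo < config.template_switch_rate + config.degradation_rate
                )
                sites = ts_sites.get(gid)
                if sites is not None and ts_mask.any():
                    pick = rng.integers(0, len(sites), size=int(ts_mask.sum()))
                    # artifact reads wobble like true-end reads
                    pos[sel[ts_mask]] = sites[pick] + jit[ts_mask]
                    origin[sel[ts_mask]] = "template_switch"
                elif ts_mask.any():
                    deg_mask = ts_mask | deg_mask
                if deg_mask.any():
                    lo, hi = truth.interiors[gid]
                    pos[sel[deg_mask]] = rng.integers(lo, hi, size=int(deg_mask.sum()))
                    origin[sel[deg_mask]] = "degradation"
            else:
                ip_mask = uo < config.internal_priming_rate
                sites = ip_sites.get(gid)
                if sites is not None and ip_mask.any():
                    pick = rng.integers(0, len(sites), size=int(ip_mask.sum()))
                    pos[sel[ip_mask]] = sites[pick] + jit[ip_mask]
                    origin[sel[ip_mask]] = "internal_priming"
        np.clip(pos, 0, config.genome_length - 1, out=pos)
        umis = _random_kmers(rng, n, config.umi_len)

        # PCR duplicates replicate the full (barcode, UMI, position) identity
        n_dup = rng.binomial(n, config.pcr_duplication_rate)
        dup_idx = rng.integers(0, n, size=n_dup) if n_dup else np.array([], dtype=int)

        base_ids = [f"{end_type.value}:{i}" for i in range(n)]
        all_idx = np.concatenate([np.arange(n), dup_idx]).astype(int)
        ids = base_ids + [f"{end_type.value}:d{j}" for j in range(n_dup)]
        frames.append(
            pd.DataFrame(
                {
                    "read_id": ids,
                    "chrom": config.chrom,
                    "pos": pos[all_idx],
                    "strand": [strand_of[gene_ids[g]] for g in gene_idx[all_idx]],
                    "end_type": end_type.value,
                    "sample_id": [f"pop{pops[c]}" for c in cell_idx[all_idx]],
                    "cell_barcode": [barcodes[c] for c in cell_idx[all_idx]],
                    "umi": [umis[i] for i in all_idx],
                }
            )
        )
        origin_frames.append(
            pd.DataFrame(
                {
                    "read_id": ids,
                    "origin": origin[all_idx],
                    "gene_id": [gene_ids[g] for g in gene_idx[all_idx]],
                    "isoform": iso_of_read[all_idx],
                    "is_duplicate": [False] * n + [True] * n_dup,
                }
            )
        )
    ends = pd.concat(frames, ignore_index=True)
    truth.cells = cells
    truth.read_origins = pd.concat(origin_frames, ignore_index=True)
    return ends, truth


def make_reference_end_beds(
    truth: SyntheticTruth, completeness: float = 1.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference TSS/TES BEDs emulating FANTOM5 / PolyA_DB3 end catalogs.

    A random ``completeness`` fraction of the distinct true ends is emitted;
    the remainder are "novel" ends by construction.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for end_type in (EndType.TSS_5p, EndType.TES_3p):
        ends = truth.true_ends(end_type)
        n_keep = int(round(completeness * len(ends)))
        keep = rng.permutation(len(ends))[:n_keep]
        sub = ends.iloc[np.sort(keep)]
        out.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "start": sub["pos"].to_numpy(),
                    "end": sub["pos"].to_numpy() + 1,
                    "name": sub["gene_id"].to_numpy(),
                    "score": 0,
                    "strand": sub["strand"].to_numpy(),
                }
            ).reset_index(drop=True)
        )
    return out[0], out[1]


def simulate_tagged_reads(
    n: int, scheme=None, seed: int = 0, tag_fraction: float = 0.5
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Raw tagged reads for exercising read selection and trimming.

    Returns 5' single reads (a ``tag_fraction`` of which carry the TSO tag),
    3' read pairs (R1 = anchor + UMI + barcode + T-run, R2 = cDNA + poly-A),
    and a truth table of the planted UMI/barcode per read id.
    """
    from .read_ends import PrimerScheme

    scheme = scheme or PrimerScheme()
    rng = np.random.default_rng(seed)
    tss_reads, pairs, rows = [], [], []
    for i in range(n):
        rid = f"sim{i}"
        insert = "".join(_BASES[rng.integers(0, 4, size=60)])
        tagged = rng.random() < tag_fraction
        seq = (scheme.tso_tag + insert) if tagged else insert
        tss_reads.append((rid, seq))
        umi = "".join(_BASES[rng.integers(0, 4, size=scheme.umi_len)])
        barcode = "".join(_BASES[rng.integers(0, 4, size=scheme.barcode_len)])
        r1 = scheme.r1_tag + umi + barcode + "T" * 30
        core = "".join(_BASES[rng.integers(0, 4, size=50)])
        if core.endswith("A"):
            core = core[:-1] + "G"
        a_len = int(rng.integers(scheme.polya_min, scheme.polya_min + 15))
        r2 = core + "A" * a_len
        pairs.append((rid, r1, r2))
        rows.append(
            {"read_id": rid, "tss_tagged": tagged, "umi": umi,
             "barcode": barcode, "polya_len": a_len, "r2_core": core}
        )
    return tss_reads, pairs, pd.DataFrame(rows)
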