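"""Gene models with per-gene TSS/TES sets, and GTF-lite serialization.

GTF-lite is the subset of GTF this package reads and writes: one ``gene``
row per gene and one ``transcript`` row per isoform, with ``gene_id`` and
``transcript_id`` attributes.  Transcript rows carry the isoform's TSS and
TES implicitly through their strand-aware genomic span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GeneModel:
    """A gene with its annotated sets of transcription start and end sites.

    ``tss_sites`` and ``tes_sites`` are 0-based single-base coordinates on
    ``strand``; the gene span covers all annotated ends.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_sites: tuple[int, ...]
    tes_sites: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.tss_sites or not self.tes_sites:
            raise ValueError(f"{self.gene_id}: needs at least one TSS and one TES")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covering all annotated ends."""
        ends = self.tss_sites + self.tes_sites
        return (min(ends), max(ends) + 1)

    @property
    def center(self) -> float:
        s, e = self.span
        return (s + e - 1) / 2.0

    def isoform_pairs(self) -> list[tuple[int, int]]:
        """(TSS, TES) pairs; sites are paired positionally, last repeated."""
        n = max(len(self.tss_sites), len(self.tes_sites))
        tss = list(self.tss_sites) + [self.tss_sites[-1]] * (n - len(self.tss_sites))
        tes = list(self.tes_sites) + [self.tes_sites[-1]] * (n - len(self.tes_sites))
        return list(zip(tss, tes))


def write_gtf_lite(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\trcatseq\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            for i, (tss, tes) in enumerate(g.isoform_pairs()):
                lo, hi = min(tss, tes), max(tss, tes)
                fh.write(
                    f"{g.chrom}\trcatseq\ttranscript\t{lo + 1}\t{hi + 1}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}"; '
                    f'transcript_id "{g.gene_id}.{i}";\n'
                )


_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_lite(path: str | Path) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, start, end, _sc, strand, _fr, attrs = line.rstrip(
                "\n"
            ).split("\t")
            if feat != "transcript":
                continue
            gid = dict(_ATTR.findall(attrs))["gene_id"]
            lo, hi = int(start) - 1, int(end) - 1  # GTF is 1-based inclusive
            tss, tes = (lo, hi) if strand == "+" else (hi, lo)
            rec = per_gene.setdefault(
                gid, {"chrom": chrom, "strand": strand, "tss": [], "tes": []}
            )
            rec["tss"].append(tss)
            rec["tes"].append(tes)
    genes = []
    for gid, rec in per_gene.items():
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss_sites=tuple(dict.fromkeys(rec["tss"])),
                tes_sites=tuple(dict.fromkeys(rec["tes"])),
            )
        )
    return genes


def degrade_annotation(
    genes: list[GeneModel], completeness: float, seed: int = 0
) -> tuple[list[GeneModel], dict[str, set[tuple[str, int]]]]:
    """Randomly drop annotated ends to emulate an incomplete end catalog.

    Each annotated end is kept with probability ``completeness``; at least one
    end per type per gene is always retained so the gene span stays defined.
    Returns the degraded models and the dropped ends per gene as
    ``{gene_id: {(end_type, pos), ...}}`` (end_type in {"TSS_5p", "TES_3p"}),
    which become "novel" ends by construction.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out, dropped = [], {}
    for g in genes:
        lost: set[tuple[str, int]] = set()

        def keep(sites: tuple[int, ...], tag: str) -> tuple[int, ...]:
            mask = rng.random(len(sites)) < completeness
            if not mask.any():
                mask[rng.integers(len(sites))] = True
            lost.update((tag, p) for p, m in zip(sites, mask) if not m)
            return tuple(p for p, m in zip(sites, mask) if m)

        out.append(
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                tss_sites=keep(g.tss_sites, "TSS_5p"),
                tes_sites=keep(g.tes_sites, "TES_3p"),
            )
        )
        dropped[g.gene_id] = lost
    return out, dropped
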