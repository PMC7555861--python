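"""Selection and trimming of end-tagged reads, and conversion of alignments
into strand-aware single-base transcript end positions.

5' reads carry the template-switching-oligo (TSO) tag and report the TSS;
3' read pairs carry the RT-primer tag on R1 (with UMI and cell barcode) and
a poly-A run on R2, whose last templated base reports the TES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class EndType(str, Enum):
    TSS_5p = "TSS_5p"
    TES_3p = "TES_3p"


@dataclass(frozen=True)
class PrimerScheme:
    """Library chemistry constants.

    ``tso_tag`` marks authentic 5' reads; trimming removes ``tso_trim`` (a
    prefix of the tag) so the template-switch-derived GGG is retained by
    default for soft-clip-aware end calling.  ``r1_tag`` anchors the 3'-side
    RT-primer segment; the UMI (``umi_len`` nt) and cell barcode
    (``barcode_len`` nt) directly follow it.  ``polya_min`` is the minimum
    trailing A-run on R2 for a pair to count as 3'-end evidence.
    """

    tso_tag: str = "GTGGTATCAACGCAGAGTACATGGG"
    tso_trim: str = "GTGGTATCAACGCAGAGTACAT"
    r1_tag: str = "AAGCAGTGGTATCAACGCAGAGT"
    umi_len: int = 8
    barcode_len: int = 16
    polya_min: int = 10
    max_tag_mismatches: int = 0
    keep_ggg: bool = True
    polya_allow_interruption: bool = False

    def __post_init__(self):
        if not self.tso_tag.startswith(self.tso_trim):
            raise ValueError("tso_trim must be a prefix of tso_tag")
        if self.umi_len <= 0:
            raise ValueError("umi_len must be > 0")
        if self.barcode_len < 0:
            raise ValueError("barcode_len must be >= 0")
        if self.polya_min < 1:
            raise ValueError("polya_min must be >= 1")
        if not 0 <= self.max_tag_mismatches <= 1:
            raise ValueError("max_tag_mismatches must be 0 or 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrimerScheme":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class EndReadRecord:
    read_id: str
    end_type: EndType
    trimmed_seq: str
    cell_barcode: str | None = None
    umi: str | None = None


@dataclass(frozen=True)
class MappedEnd:
    """One strand-aware genomic end position derived from one read."""

    chrom: str
    pos: int
    strand: str
    end_type: EndType
    sample_id: str
    cell_barcode: str | None = None
    umi: str | None = None


ENDS_COLUMNS = ["read_id", "chrom", "pos", "strand", "end_type", "sample_id",
                "cell_barcode", "umi"]


def find_tag(seq: str, tag: str, max_mismatches: int = 0) -> int:
    """Leftmost start of ``tag`` in ``seq`` allowing ``max_mismatches``; -1 if absent."""
    if max_mismatches == 0:
        return seq.find(tag)
    n, m = len(seq), len(tag)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], tag):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return i
    return -1


def select_tss_reads(
    reads: Iterable[tuple[str, str]], scheme: PrimerScheme | None = None
) -> list[EndReadRecord]:
    """Keep reads containing the TSO tag and trim the TSO away.

    ``reads`` yields ``(read_id, sequence)``.  The returned sequence starts at
    the first base after the trimmed TSO; the GGG from template switching is
    retained when ``scheme.keep_ggg`` (default) and removed otherwise.
    Reads with characters outside ACGTN are skipped with a warning.
    """
    scheme = scheme or PrimerScheme()
    trim_len = len(scheme.tso_trim) if scheme.keep_ggg else len(scheme.tso_tag)
    out = []
    for read_id, seq in reads:
        seq = seq.upper()
        if not _VALID_BASES.issuperset(seq):
            log.warning("read %s: malformed sequence characters; skipped", read_id)
            continue
        i = find_tag(seq, scheme.tso_tag, scheme.max_tag_mismatches)
        if i < 0:
            continue
        out.append(
            EndReadRecord(
                read_id=read_id,
                end_type=EndType.TSS_5p,
                trimmed_seq=seq[i + trim_len :],
            )
        )
    return out


def trailing_polya_run(seq: str, scheme: PrimerScheme) -> int:
    """Number of trailing bases removed as the 3' poly-A run.

    Strict mode removes the maximal trailing run of A.  With
    ``polya_allow_interruption`` one non-A base inside the run is tolerated
    provided the run resumes for at least ``polya_min`` further bases.
    """
    n = len(seq)
    run1 = 0
    while run1 < n and seq[n - 1 - run1] == "A":
        run1 += 1
    if not scheme.polya_allow_interruption:
        return run1
    i = n - 1 - run1
    if run1 == 0 or i < 0:
        return run1
    run2 = 0
    j = i - 1
    while j >= 0 and seq[j] == "A":
        run2 += 1
        j -= 1
    if run2 >= scheme.polya_min:
        return run1 + 1 + run2
    return run1


def trim_polya(seq: str, scheme: PrimerScheme | None = None) -> str:
    """Remove the trailing poly-A run (idempotent: re-trimming is a no-op)."""
    scheme = scheme or PrimerScheme()
    k = trailing_polya_run(seq, scheme)
    return seq[: len(seq) - k] if k else seq


def parse_r1_tag(seq: str, scheme: PrimerScheme) -> tuple[str, str] | None:
    """UMI and cell barcode following the R1 RT-primer anchor, or None."""
    i = find_tag(seq, scheme.r1_tag, scheme.max_tag_mismatches)
    if i < 0:
        return None
    start = i + len(scheme.r1_tag)
    end = start + scheme.umi_len + scheme.barcode_len
    if end > len(seq):
        return None
    umi = seq[start : start + scheme.umi_len]
    barcode = seq[start + scheme.umi_len : end]
    return umi, barcode


def select_polya_pairs(
    pairs: Iterable[tuple[str, str, str]], scheme: PrimerScheme | None = None
) -> list[EndReadRecord]:
    """Keep pairs with the 3' tag on R1 and >= ``polya_min`` trailing A on R2.

    ``pairs`` yields ``(read_id, r1_seq, r2_seq)``.  The trailing A-run is
    trimmed from R2; UMI then cell barcode are parsed from the R1 tag segment.
    """
    scheme = scheme or PrimerScheme()
    out = []
    for read_id, r1, r2 in pairs:
        r1, r2 = r1.upper(), r2.upper()
        if not _VALID_BASES.issuperset(r1 + r2):
            log.warning("pair %s: malformed sequence characters; skipped", read_id)
            continue
        parsed = parse_r1_tag(r1, scheme)
        if parsed is None:
            continue
        run = trailing_polya_run(r2, scheme)
        if run < scheme.polya_min:
            continue
        umi, barcode = parsed
        out.append(
            EndReadRecord(
                read_id=read_id,
                end_type=EndType.TES_3p,
                trimmed_seq=r2[: len(r2) - run],
                cell_barcode=barcode or None,
                umi=umi,
            )
        )
    return out


def _exclusion_trees(bed: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if bed is None:
        return trees
    for chrom, sub in bed.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def _parse_read_name(name: str) -> tuple[str, str | None, str | None]:
    """Read names of the form ``id|barcode|umi`` carry cell identity."""
    parts = name.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1] or None, parts[2] or None
    return name, None, None


def extract_mapped_ends(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    end_type: EndType | str,
    sample_id: str = "sample",
    exclusion_bed: pd.DataFrame | None = None,
    require_sorted: bool = True,
) -> tuple[list[MappedEnd], dict[str, int]]:
    """Convert alignment records into single-base transcript end positions.

    Keeps uniquely mapped primary alignments; drops multimappers (secondary/
    supplementary flags or NH > 1) and alignments overlapping the exclusion
    regions (e.g. an rRNA surrogate BED).  The transcript strand equals the
    alignment strand; for ``TSS_5p`` the reported position is the 5'-most
    aligned base in transcript orientation, for ``TES_3p`` the 3'-most (the
    last templated base before the poly-A).  Soft-clipped bases (including a
    retained template-switch GGG) are outside the aligned span, so the end is
    the first genome-matching base.

    Returns the retained ends and per-category drop counts; counts are
    conserved: ``retained + sum(drops) == number of input records``.
    """
    end_type = EndType(end_type)
    trees = _exclusion_trees(exclusion_bed)
    opened = None
    if isinstance(alignments, (str, Path)):
        opened = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = opened
    else:
        records = alignments
    counts = {"retained": 0, "unmapped": 0, "multimapped": 0, "excluded": 0}
    ends: list[MappedEnd] = []
    seen_refs: list[str] = []
    last_pos = -1
    try:
        for seg in records:
            if seg.is_unmapped or seg.reference_name is None:
                counts["unmapped"] += 1
                continue
            ref = seg.reference_name
            if require_sorted:
                if not seen_refs or seen_refs[-1] != ref:
                    if ref in seen_refs:
                        raise ValueError(
                            f"alignment input not coordinate-sorted at record "
                            f"{seg.query_name!r}: contig {ref} seen out of order"
                        )
                    seen_refs.append(ref)
                    last_pos = -1
                if seg.reference_start < last_pos:
                    raise ValueError(
                        f"alignment input not coordinate-sorted at record "
                        f"{seg.query_name!r} ({ref}:{seg.reference_start})"
                    )
                last_pos = seg.reference_start
            nh = seg.get_tag("NH") if seg.has_tag("NH") else 1
            if seg.is_secondary or seg.is_supplementary or nh > 1:
                counts["multimapped"] += 1
                continue
            tree = trees.get(ref)
            if tree is not None and tree.overlap(seg.reference_start, seg.reference_end):
                counts["excluded"] += 1
                continue
            strand = "-" if seg.is_reverse else "+"
            five_prime = seg.reference_start if strand == "+" else seg.reference_end - 1
            three_prime = seg.reference_end - 1 if strand == "+" else seg.reference_start
            pos = five_prime if end_type is EndType.TSS_5p else three_prime
            _rid, barcode, umi = _parse_read_name(seg.query_name or "")
            ends.append(
                MappedEnd(
                    chrom=ref,
                    pos=int(pos),
                    strand=strand,
                    end_type=end_type,
                    sample_id=sample_id,
                    cell_barcode=barcode,
                    umi=umi,
                )
            )
            counts["retained"] += 1
    finally:
        if opened is not None:
            opened.close()
    return ends, counts


def ends_to_frame(ends: Sequence[MappedEnd]) -> pd.DataFrame:
    """Tabular view of mapped ends (one row per read end)."""
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(ends))],
            "chrom": [e.chrom for e in ends],
            "pos": pd.array([e.pos for e in ends], dtype="int64"),
            "strand": [e.strand for e in ends],
            "end_type": [EndType(e.end_type).value for e in ends],
            "sample_id": [e.sample_id for e in ends],
            "cell_barcode": [e.cell_barcode for e in ends],
            "umi": [e.umi for e in ends],
        }
    )


def ends_frame_to_bed(ends: pd.DataFrame) -> pd.DataFrame:
    """6-column BED with name ``sample:barcode:umi:end_type`` and score 1."""
    name = (
        ends["sample_id"].astype(str)
        + ":" + ends["cell_barcode"].fillna("").astype(str)
        + ":" + ends["umi"].fillna("").astype(str)
        + ":" + ends["end_type"].astype(str)
    )
    return pd.DataFrame(
        {
            "chrom": ends["chrom"],
            "start": ends["pos"].astype(int),
            "end": ends["pos"].astype(int) + 1,
            "name": name,
            "score": 1,
            "strand": ends["strand"],
        }
    )


def bed_to_ends_frame(bed: pd.DataFrame) -> pd.DataFrame:
    parts = bed["name"].astype(str).str.split(":", expand=True)
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(bed))],
            "chrom": bed["chrom"].astype(str),
            "pos": bed["start"].astype(int),
            "strand": bed["strand"].astype(str),
            "end_type": parts[3],
            "sample_id": parts[0],
            "cell_barcode": parts[1].replace("", None),
            "umi": parts[2].replace("", None),
        }
    )
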