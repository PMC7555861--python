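"""Distance-based clustering of single-base end counts into TSS/TES peaks.

Positions whose per-sample signal passes a threshold (in tags-per-million by
default) seed clusters; seeds on the same contig and strand are merged by
single-linkage along the coordinate when the gap between adjacent seeds is at
most ``max_dist``.  Each peak is represented by its dominant position, the
single base carrying the maximal pooled signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .read_ends import EndType

log = logging.getLogger(__name__)

KEY_COLUMNS = ["chrom", "strand", "pos"]


@dataclass(frozen=True)
class PeakCallingParams:
    """Clustering parameters (defaults match CAGEr's distclu usage:
    threshold 3 TPM in at least one sample, singletons kept, 20 bp max gap)."""

    threshold: float = 3.0
    threshold_is_tpm: bool = True
    nr_pass_threshold: int = 1
    max_dist: int = 20
    remove_singletons: bool = False
    keep_singletons_above: float = 10.0

    def __post_init__(self):
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.nr_pass_threshold < 1:
            raise ValueError("nr_pass_threshold must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeakCallingParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class TagCluster:
    """A called peak: a half-open span of clustered positions with its
    dominant (maximal pooled signal) single-base position."""

    peak_id: str
    chrom: str
    strand: str
    start: int
    end: int
    dominant_pos: int
    dominant_signal: float
    total_signal: float
    n_positions: int
    end_type: EndType

    def __post_init__(self):
        if not self.start <= self.dominant_pos < self.end:
            raise ValueError(f"{self.peak_id}: dominant_pos outside span")
        if self.dominant_signal > self.total_signal + 1e-9:
            raise ValueError(f"{self.peak_id}: dominant_signal > total_signal")
        if self.n_positions < 1:
            raise ValueError(f"{self.peak_id}: empty cluster")

    @property
    def width(self) -> int:
        return self.end - self.start


class EndCountTrack:
    """Per-position end counts for one or more samples.

    ``counts`` has key columns (chrom, strand, pos) — sorted, unique — plus
    one integer column per sample.  ``library_sizes`` default to the column
    sums (total counted ends per sample).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: pd.Series | None = None,
        sort: bool = True,
    ):
        counts = counts.copy()
        for col in KEY_COLUMNS:
            if col not in counts.columns:
                raise ValueError(f"counts missing key column {col!r}")
        if sort:
            counts = counts.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(
                drop=True
            )
        self.counts = counts
        self.samples = [c for c in counts.columns if c not in KEY_COLUMNS]
        if not self.samples:
            raise ValueError("track has no sample columns")
        if counts.duplicated(KEY_COLUMNS).any():
            raise ValueError("duplicate (chrom, strand, pos) rows in track")
        if library_sizes is None:
            library_sizes = counts[self.samples].sum()
        self.library_sizes = library_sizes.astype(float)

    @classmethod
    def from_ends(
        cls,
        ends: pd.DataFrame,
        sample_col: str = "sample_id",
        mode: str = "reads",
    ) -> "EndCountTrack":
        """Pivot mapped ends into a per-position count track.

        ``mode='umi'`` counts distinct (cell_barcode, umi) pairs per position
        per sample instead of raw reads.
        """
        if mode not in ("reads", "umi"):
            raise ValueError("mode must be 'reads' or 'umi'")
        df = ends
        if mode == "umi":
            df = df.drop_duplicates(
                subset=[sample_col, "cell_barcode", "umi"] + KEY_COLUMNS
            )
        tab = (
            df.groupby(KEY_COLUMNS + [sample_col], observed=True)
            .size()
            .unstack(sample_col, fill_value=0)
            .reset_index()
        )
        tab.columns.name = None
        return cls(tab)

    def is_sorted(self) -> bool:
        keys = self.counts[KEY_COLUMNS]
        return keys.equals(keys.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True))

    def tpm(self) -> pd.DataFrame:
        """Per-position tags-per-million per sample (sums to 1e6 per sample)."""
        out = self.counts[self.samples].astype(float).copy()
        for s in self.samples:
            lib = self.library_sizes[s]
            if lib <= 0:
                log.warning("sample %s has zero library size; TPM set to 0", s)
                out[s] = 0.0
            else:
                out[s] = out[s] * (1e6 / lib)
        return out

    def total_signal(self, tpm: bool = True) -> float:
        mat = self.tpm() if tpm else self.counts[self.samples]
        return float(mat.to_numpy().sum())


def tpm_normalize(track: EndCountTrack) -> pd.DataFrame:
    """Tags-per-million signal per position and sample."""
    return track.tpm()


def pool_samples(
    track: EndCountTrack, grouping: Mapping[str, str] | None = None
) -> EndCountTrack:
    """Sum counts (and library sizes) over samples, per group.

    ``grouping`` maps sample name to group name; omitted samples are dropped,
    ``None`` pools everything into a single ``pooled`` sample.
    """
    if grouping is None:
        grouping = {s: "pooled" for s in track.samples}
    groups: dict[str, list[str]] = {}
    for s, g in grouping.items():
        if s not in track.samples:
            raise KeyError(f"unknown sample {s!r}")
        groups.setdefault(g, []).append(s)
    out = track.counts[KEY_COLUMNS].copy()
    libs = {}
    for g, members in groups.items():
        out[g] = track.counts[members].sum(axis=1)
        libs[g] = track.library_sizes[members].sum()
    sub = EndCountTrack(out, pd.Series(libs), sort=False)
    # drop all-zero rows introduced by sample subsetting
    mask = sub.counts[list(groups)].sum(axis=1) > 0
    return EndCountTrack(sub.counts[mask].reset_index(drop=True), pd.Series(libs), sort=False)


def call_peaks(
    track: EndCountTrack,
    params: PeakCallingParams | None = None,
    end_type: EndType | str = EndType.TSS_5p,
) -> list[TagCluster]:
    """Cluster above-threshold positions into peaks (distclu semantics).

    A position seeds a cluster when its signal passes ``threshold`` in at
    least ``nr_pass_threshold`` samples (per-sample TPM when
    ``threshold_is_tpm``, raw counts otherwise).  Adjacent seeds on the same
    chrom and strand merge when their coordinate gap is <= ``max_dist``
    (single linkage).  The cluster span covers seeds only; sub-threshold
    positions inside the span contribute to the total (pooled TPM) signal and
    may carry the dominant position, but cannot seed or extend a cluster.
    Dominant-position ties resolve to the 5'-most position in transcript
    orientation.  Singleton (width-1) clusters are dropped only when
    ``remove_singletons`` and their total signal is <= ``keep_singletons_above``.
    """
    params = params or PeakCallingParams()
    end_type = EndType(end_type)
    if not track.is_sorted():
        raise ValueError("track must be sorted by (chrom, strand, pos)")
    signal = track.tpm() if params.threshold_is_tpm else track.counts[track.samples].astype(float)
    pass_mat = (signal >= params.threshold).sum(axis=1).to_numpy()
    seed_mask = pass_mat >= params.nr_pass_threshold
    pooled = track.tpm().sum(axis=1).to_numpy()

    clusters: list[TagCluster] = []
    prefix = "tss" if end_type is EndType.TSS_5p else "tes"
    keys = track.counts[KEY_COLUMNS]
    idx = np.arange(len(keys))
    for (chrom, strand), grp_idx in keys.groupby(["chrom", "strand"], sort=True).groups.items():
        gi = np.asarray(grp_idx)
        pos = keys["pos"].to_numpy()[gi]
        g_seed = seed_mask[gi]
        g_pooled = pooled[gi]
        seeds = np.flatnonzero(g_seed)
        if seeds.size == 0:
            continue
        seed_pos = pos[seeds]
        breaks = np.flatnonzero(np.diff(seed_pos) > params.max_dist)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks, [seeds.size - 1]))
        for a, b in zip(starts, stops):
            lo_pos, hi_pos = int(seed_pos[a]), int(seed_pos[b])
            member = (pos >= lo_pos) & (pos <= hi_pos) & (g_pooled > 0)
            m_pos = pos[member]
            m_sig = g_pooled[member]
            total = float(m_sig.sum())
            best = m_sig.max()
            cand = m_pos[m_sig == best]
            dom = int(cand.min() if strand == "+" else cand.max())
            cl = TagCluster(
                peak_id=f"{prefix}_{len(clusters):05d}",
                chrom=str(chrom),
                strand=str(strand),
                start=lo_pos,
                end=hi_pos + 1,
                dominant_pos=dom,
                dominant_signal=float(best),
                total_signal=total,
                n_positions=int(member.sum()),
                end_type=end_type,
            )
            if (
                params.remove_singletons
                and cl.width == 1
                and cl.total_signal <= params.keep_singletons_above
            ):
                continue
            clusters.append(cl)
    return clusters


def clusters_to_frame(clusters: Sequence[TagCluster]) -> pd.DataFrame:
    """BED6+ view: extra columns dominant_pos, dominant_tpm, total_tpm,
    n_positions, end_type."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "name": [c.peak_id for c in clusters],
            "score": [round(c.total_signal, 4) for c in clusters],
            "strand": [c.strand for c in clusters],
            "dominant_pos": [c.dominant_pos for c in clusters],
            "dominant_tpm": [c.dominant_signal for c in clusters],
            "total_tpm": [c.total_signal for c in clusters],
            "n_positions": [c.n_positions for c in clusters],
            "end_type": [c.end_type.value for c in clusters],
        }
    )


def frame_to_clusters(df: pd.DataFrame) -> list[TagCluster]:
    return [
        TagCluster(
            peak_id=str(r.name_) if hasattr(r, "name_") else str(r["name"]),
            chrom=str(r["chrom"]),
            strand=str(r["strand"]),
            start=int(r["start"]),
            end=int(r["end"]),
            dominant_pos=int(r["dominant_pos"]),
            dominant_signal=float(r["dominant_tpm"]),
            total_signal=float(r["total_tpm"]),
            n_positions=int(r["n_positions"]),
            end_type=EndType(r["end_type"]),
        )
        for _, r in df.iterrows()
    ]
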