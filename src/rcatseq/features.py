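"""Per-peak feature engineering for TRUE/FALSE end classification.

Three named feature groups are built for every peak:

``distribution``
    Read-distribution summaries (signal, width, dominant fraction, position
    within the assigned gene) plus total motif occurrence counts.
``motif``
    Positional occurrence blocks for true-end motifs: 3 promoter motifs
    (BREu ``SSRCGCC``, TATA-box ``TATAWAWR``, BREd ``RTDKKKK``) x 50 upstream
    offsets = 150 columns for TSS peaks, and 13 polyadenylation-signal
    hexamers x 50 offsets = 650 columns for TES peaks.  Promoter motifs allow
    up to 2 mismatches; PAS hexamers are matched exactly.
``artifact``
    Evidence for false-positive ends: downstream genomic A-content (internal
    priming) for TES peaks; genomic G/GGG at the start site and upstream
    C-content (internal template switching) for TSS peaks.

All values are normalized to [0, 1]; the fitted normalization is stored so it
can be re-applied verbatim at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .io import GenomeSource, dump_json, load_json, revcomp
from .peaks import TagCluster
from .read_ends import EndType

# IUPAC nucleotide codes as 4-bit masks (A=1, C=2, G=4, T=8).
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}
# In observed sequence, N (and pad) matches nothing.
_SEQ_MASKS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}

TSS_MOTIFS: tuple[tuple[str, str], ...] = (
    ("BREu", "SSRCGCC"),
    ("TATA", "TATAWAWR"),
    ("BREd", "RTDKKKK"),
)
TES_PAS_HEXAMERS: tuple[str, ...] = (
    "AATAAA", "ATTAAA", "AAGAAA", "AATAGA", "AATACA", "AATATA", "AATGAA",
    "AGTAAA", "ACTAAA", "GATAAA", "CATAAA", "TATAAA", "TTTAAA",
)


@dataclass(frozen=True)
class MotifSet:
    tss_motifs: tuple[tuple[str, str], ...] = TSS_MOTIFS
    tes_motifs: tuple[str, ...] = TES_PAS_HEXAMERS
    max_mismatch: int = 2  # applies to TSS promoter motifs only
    window: int = 50

    def __post_init__(self):
        for _, pat in self.tss_motifs:
            _encode_pattern(pat)
        for pat in self.tes_motifs:
            _encode_pattern(pat)


def _encode_pattern(pattern: str) -> np.ndarray:
    try:
        return np.array([IUPAC_MASKS[c] for c in pattern.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"invalid IUPAC character {e.args[0]!r} in pattern") from None


def _encode_seq(seq: str) -> np.ndarray:
    try:
        return np.array([_SEQ_MASKS[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"invalid sequence character {e.args[0]!r}") from None


DEFAULT_MOTIFS = MotifSet()


def scan_motif(seq: str, pattern: str, max_mismatch: int = 0) -> np.ndarray:
    """Binary match indicator per offset of ``pattern`` in ``seq``.

    A sequence base matches a pattern position when it belongs to the IUPAC
    code's base set; the mismatch count at an offset is the number of
    violating positions, and the indicator is 1 when it is <= ``max_mismatch``.
    Returns a vector over offsets ``0 .. len(seq) - len(pattern)`` (empty when
    the sequence is shorter than the pattern).  ``N`` in the sequence never
    matches.
    """
    pat = _encode_pattern(pattern)
    s = _encode_seq(seq)
    m = len(pat)
    if len(s) < m:
        return np.zeros(0, dtype=np.int8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mismatches = ((windows & pat) == 0).sum(axis=1)
    return (mismatches <= max_mismatch).astype(np.int8)


def upstream_window(
    genome: GenomeSource, chrom: str, strand: str, pos: int, n: int
) -> str:
    """The ``n`` nt immediately upstream of ``pos`` in transcript orientation,
    returned 5'->3' and ending just before ``pos`` (N-padded at contig edges)."""
    if strand == "+":
        return genome.fetch(chrom, pos - n, pos)
    return revcomp(genome.fetch(chrom, pos + 1, pos + 1 + n))


def downstream_window(
    genome: GenomeSource, chrom: str, strand: str, pos: int, n: int
) -> str:
    """The ``n`` nt immediately downstream of ``pos`` (excluded), 5'->3' in
    transcript orientation."""
    if strand == "+":
        return genome.fetch(chrom, pos + 1, pos + 1 + n)
    return revcomp(genome.fetch(chrom, pos - n, pos))


def at_site_window(
    genome: GenomeSource, chrom: str, strand: str, pos: int, n: int
) -> str:
    """``n`` nt starting at ``pos`` itself, 5'->3' in transcript orientation."""
    if strand == "+":
        return genome.fetch(chrom, pos, pos + n)
    return revcomp(genome.fetch(chrom, pos - n + 1, pos + 1))


def _positional_block(
    window_seq: str, name: str, pattern: str, max_mismatch: int, window: int
) -> pd.Series:
    """One motif's 50-offset indicator block.

    Offset ``k`` (1..window) is 1 when a motif occurrence starts (5'-most
    base, transcript orientation) exactly ``k`` nt upstream of the dominant
    position; occurrences must lie fully inside the window, so offsets
    smaller than the pattern length are structurally 0.
    """
    hits = scan_motif(window_seq, pattern, max_mismatch)
    vals = np.zeros(window, dtype=np.int8)
    # window_seq index j corresponds to upstream distance (window - j)
    for j in np.flatnonzero(hits):
        k = window - int(j)
        if 1 <= k <= window:
            vals[k - 1] = 1
    return pd.Series(
        vals, index=[f"{name}_up{k:02d}" for k in range(1, window + 1)], dtype=float
    )


def tss_motif_features(
    genome: GenomeSource, peak: TagCluster, motifs: MotifSet = DEFAULT_MOTIFS
) -> pd.Series:
    """150-vector: 3 promoter motifs x 50 strand-aware upstream offsets."""
    win = upstream_window(genome, peak.chrom, peak.strand, peak.dominant_pos, motifs.window)
    parts = [
        _positional_block(win, name, pat, motifs.max_mismatch, motifs.window)
        for name, pat in motifs.tss_motifs
    ]
    return pd.concat(parts)


def tes_motif_features(
    genome: GenomeSource,
    peak: TagCluster,
    motifs: MotifSet = DEFAULT_MOTIFS,
    window_mode: str = "upstream",
) -> pd.Series:
    """650-vector: 13 PAS hexamers x 50 offsets, exact matching.

    The 50 offsets default to the 50 nt upstream of the cleavage position
    (PAS lies 10-30 nt upstream of cleavage); ``window_mode='centered'``
    instead uses a +-25 nt window around the cleavage site, with offsets
    numbered from its 3' edge.
    """
    if window_mode == "upstream":
        win = upstream_window(genome, peak.chrom, peak.strand, peak.dominant_pos, motifs.window)
    elif window_mode == "centered":
        half = motifs.window // 2
        up = upstream_window(genome, peak.chrom, peak.strand, peak.dominant_pos, half)
        down = at_site_window(genome, peak.chrom, peak.strand, peak.dominant_pos, motifs.window - half)
        win = up + down
    else:
        raise ValueError("window_mode must be 'upstream' or 'centered'")
    parts = [
        _positional_block(win, pat, pat, 0, motifs.window) for pat in motifs.tes_motifs
    ]
    return pd.concat(parts)


def _motif_counts(
    genome: GenomeSource, peak: TagCluster, motifs: MotifSet
) -> pd.Series:
    """Total occurrences of each end-type motif in the upstream window
    (distribution-group companions to the positional blocks)."""
    win = upstream_window(genome, peak.chrom, peak.strand, peak.dominant_pos, motifs.window)
    if peak.end_type is EndType.TSS_5p:
        items = [
            (f"count_{name}", int(scan_motif(win, pat, motifs.max_mismatch).sum()))
            for name, pat in motifs.tss_motifs
        ]
    else:
        items = [
            (f"count_{pat}", int(scan_motif(win, pat, 0).sum()))
            for pat in motifs.tes_motifs
        ]
    return pd.Series(dict(items), dtype=float)


def distribution_features(
    peak: TagCluster, gene_span: tuple[int, int] | None = None
) -> pd.Series:
    """Raw (pre-normalization) read-distribution features.

    ``gene_rel_pos`` is the dominant position within the assigned gene span in
    transcript orientation: 0 at the annotated gene 5' end, 1 at the 3' end,
    0.5 when unassigned.
    """
    rel = 0.5
    if gene_span is not None:
        s, e = gene_span
        if e > s + 1:
            frac = (peak.dominant_pos - s) / (e - 1 - s)
            rel = float(np.clip(frac if peak.strand == "+" else 1.0 - frac, 0.0, 1.0))
    total = peak.total_signal
    return pd.Series(
        {
            "total_signal": total,
            "dominant_signal": peak.dominant_signal,
            "width": float(peak.width),
            "n_positions": float(peak.n_positions),
            "dominant_fraction": peak.dominant_signal / total if total > 0 else 0.0,
            "gene_rel_pos": rel,
            "log10_total_signal": float(np.log10(total + 1.0)),
        }
    )


def _longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def artifact_features(
    genome: GenomeSource, peak: TagCluster, a_window: int = 20, a_flag_threshold: float = 0.6
) -> pd.Series:
    """False-positive evidence features, strand-aware.

    TES peaks: A fraction and longest A-run (scaled by window size) in the
    ``a_window`` nt genomic window downstream of the cleavage site, plus a
    binary flag for A fraction >= ``a_flag_threshold`` — internal-priming
    evidence.  TSS peaks: G fraction and GGG presence in the 3 nt at/just
    downstream of the dominant position and the upstream C fraction —
    template-switch evidence.  Fractions use available (non-N) bases only.
    """
    chrom, strand, pos = peak.chrom, peak.strand, peak.dominant_pos
    if peak.end_type is EndType.TES_3p:
        win = downstream_window(genome, chrom, strand, pos, a_window)
        avail = sum(1 for c in win if c != "N")
        a_frac = win.count("A") / avail if avail else 0.0
        return pd.Series(
            {
                "downstream_a_fraction": a_frac,
                "downstream_a_run": _longest_run(win, "A") / a_window,
                "internal_priming_flag": float(a_frac >= a_flag_threshold),
            }
        )
    site = at_site_window(genome, chrom, strand, pos, 3)
    site_avail = sum(1 for c in site if c != "N")
    up = upstream_window(genome, chrom, strand, pos, a_window)
    up_avail = sum(1 for c in up if c != "N")
    return pd.Series(
        {
            "site_g_fraction": site.count("G") / site_avail if site_avail else 0.0,
            "site_ggg_flag": float(site == "GGG"),
            "upstream_c_fraction": up.count("C") / up_avail if up_avail else 0.0,
        }
    )


# ---------------------------------------------------------------------------
# Normalization

# Heavy-tailed signal features get rank-based quantile normalization; other
# unbounded features get min-max; fractions, flags and motif indicators are
# already in [0, 1] and pass through unchanged.
_QUANTILE_COLS = {"total_signal", "dominant_signal", "log10_total_signal"}
_MINMAX_COLS = {"width", "n_positions"}


def _column_kind(col: str) -> str:
    if col in _QUANTILE_COLS:
        return "quantile"
    if col in _MINMAX_COLS or col.startswith("count_"):
        return "minmax"
    return "identity"


class Normalizer:
    """Per-column [0, 1] normalization with stored, re-applicable parameters.

    min-max: ``(x - min) / (max - min)`` with the training extremes, clipped;
    quantile: ``rank(x) / n`` via right-sided search into the sorted training
    values.  Applying a fitted normalizer to its own training data reproduces
    the training matrix exactly.
    """

    def __init__(self, params: dict | None = None):
        self.params: dict[str, dict] = params or {}

    def fit(self, df: pd.DataFrame) -> "Normalizer":
        self.params = {}
        for col in df.columns:
            kind = _column_kind(col)
            if kind == "minmax":
                lo, hi = float(df[col].min()), float(df[col].max())
                self.params[col] = {"kind": "minmax", "min": lo, "max": hi}
            elif kind == "quantile":
                ref = np.sort(df[col].to_numpy(dtype=float))
                self.params[col] = {"kind": "quantile", "ref": ref.tolist()}
            else:
                self.params[col] = {"kind": "identity"}
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if set(df.columns) != set(self.params):
            raise ValueError("feature columns do not match fitted normalizer")
        out = df.astype(float).copy()
        for col, p in self.params.items():
            if p["kind"] == "minmax":
                span = p["max"] - p["min"]
                if span <= 0:
                    out[col] = 0.0
                else:
                    out[col] = ((out[col] - p["min"]) / span).clip(0.0, 1.0)
            elif p["kind"] == "quantile":
                ref = np.asarray(p["ref"], dtype=float)
                out[col] = np.searchsorted(ref, out[col].to_numpy(), side="right") / len(ref)
        return out

    def to_dict(self) -> dict:
        return self.params

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(params=d)


@dataclass
class FeatureMatrix:
    """Normalized per-peak feature vectors with named group labels.

    ``X`` is peaks x features (values in [0, 1]); ``groups`` maps every
    column to its feature group; ``normalizer`` holds the fitted
    normalization for reuse at prediction time.
    """

    X: pd.DataFrame
    groups: dict[str, str]
    normalizer: Normalizer
    end_type: EndType

    def __post_init__(self):
        if set(self.X.columns) != set(self.groups):
            raise ValueError("groups must label exactly the matrix columns")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    def columns_in_group(self, group: str) -> list[str]:
        return [c for c in self.X.columns if self.groups[c] == group]

    @property
    def motif_block_width(self) -> int:
        return len(self.columns_in_group("motif"))

    def save(self, tsv_path: str | Path) -> None:
        self.X.to_csv(tsv_path, sep="\t", index_label="peak_id")
        sidecar = Path(str(tsv_path) + ".json")
        dump_json(
            {
                "end_type": self.end_type.value,
                "groups": self.groups,
                "normalizer": self.normalizer.to_dict(),
            },
            sidecar,
        )

    @classmethod
    def load(cls, tsv_path: str | Path) -> "FeatureMatrix":
        X = pd.read_csv(tsv_path, sep="\t", index_col="peak_id")
        meta = load_json(Path(str(tsv_path) + ".json"))
        return cls(
            X=X,
            groups=meta["groups"],
            normalizer=Normalizer.from_dict(meta["normalizer"]),
            end_type=EndType(meta["end_type"]),
        )


def assemble_features(
    peaks: Sequence[TagCluster],
    genome: GenomeSource | Mapping[str, str] | str | Path,
    end_type: EndType | str,
    motifs: MotifSet = DEFAULT_MOTIFS,
    genes: Sequence[GeneModel] | None = None,
    gene_spans: Mapping[str, tuple[int, int]] | None = None,
    normalizer: Normalizer | None = None,
    tes_window_mode: str = "upstream",
) -> FeatureMatrix:
    """Build the full per-peak feature matrix for one end type.

    Column order is deterministic: distribution block (including per-motif
    occurrence counts), then the positional motif block (150 columns for TSS,
    650 for TES), then the artifact block.  Passing a fitted ``normalizer``
    re-applies stored training normalization (prediction time); otherwise a
    new one is fitted to this matrix.
    """
    end_type = EndType(end_type)
    genome = GenomeSource(genome)
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peak ids")
    if gene_spans is None and genes is not None:
        from .isoforms import assign_peaks

        gene_by_id = {g.gene_id: g for g in genes}
        gene_spans = {
            a.peak_id: gene_by_id[a.gene_id].span
            for a in assign_peaks(peaks, list(genes))
            if a.gene_id is not None
        }
    gene_spans = gene_spans or {}

    rows = []
    for p in peaks:
        if EndType(p.end_type) is not end_type:
            raise ValueError(f"peak {p.peak_id} has end_type {p.end_type}, expected {end_type}")
        dist = pd.concat(
            [distribution_features(p, gene_spans.get(p.peak_id)), _motif_counts(genome, p, motifs)]
        )
        if end_type is EndType.TSS_5p:
            motif = tss_motif_features(genome, p, motifs)
        else:
            motif = tes_motif_features(genome, p, motifs, window_mode=tes_window_mode)
        art = artifact_features(genome, p)
        rows.append(pd.concat([dist, motif, art]))
    if rows:
        raw = pd.DataFrame(rows, index=pd.Index(ids, name="peak_id"))
    else:
        # preserve the dimensional contract even for empty peak sets
        proto_dist = pd.concat(
            [
                distribution_features(
                    TagCluster("proto", "x", "+", 0, 1, 0, 1.0, 1.0, 1, end_type)
                ),
                pd.Series(
                    {
                        f"count_{n if end_type is EndType.TSS_5p else p}": 0.0
                        for n, p in (
                            [(n, n) for n, _ in motifs.tss_motifs]
                            if end_type is EndType.TSS_5p
                            else [(p, p) for p in motifs.tes_motifs]
                        )
                    }
                ),
            ]
        )
        names = (
            [f"{n}_up{k:02d}" for n, _ in motifs.tss_motifs for k in range(1, motifs.window + 1)]
            if end_type is EndType.TSS_5p
            else [f"{p}_up{k:02d}" for p in motifs.tes_motifs for k in range(1, motifs.window + 1)]
        )
        art_names = (
            ["site_g_fraction", "site_ggg_flag", "upstream_c_fraction"]
            if end_type is EndType.TSS_5p
            else ["downstream_a_fraction", "downstream_a_run", "internal_priming_flag"]
        )
        raw = pd.DataFrame(
            columns=list(proto_dist.index) + names + art_names,
            index=pd.Index([], name="peak_id"),
            dtype=float,
        )

    n_dist = 7 + (len(motifs.tss_motifs) if end_type is EndType.TSS_5p else len(motifs.tes_motifs))
    n_motif = motifs.window * (
        len(motifs.tss_motifs) if end_type is EndType.TSS_5p else len(motifs.tes_motifs)
    )
    groups = {}
    for i, col in enumerate(raw.columns):
        if i < n_dist:
            groups[col] = "distribution"
        elif i < n_dist + n_motif:
            groups[col] = "motif"
        else:
            groups[col] = "artifact"

    if normalizer is None:
        normalizer = Normalizer().fit(raw)
    X = normalizer.transform(raw)
    return FeatureMatrix(X=X, groups=groups, normalizer=normalizer, end_type=end_type)
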