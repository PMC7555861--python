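"""Readers and writers for the plain-text formats used across the pipeline.

Coordinates are 0-based half-open throughout (BED convention); single-base
end positions are emitted as ``[pos, pos + 1)`` intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from pyfaidx import Fasta

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSource:
    """Strand-agnostic random access to genome sequence.

    Wraps either an indexed FASTA file (via pyfaidx) or an in-memory
    ``{contig: sequence}`` mapping.  ``fetch`` pads with ``N`` outside contig
    bounds so window extraction near contig edges never fails; ``N`` never
    matches any motif code downstream.
    """

    def __init__(self, source: str | Path | Mapping[str, str] | "GenomeSource"):
        if isinstance(source, GenomeSource):
            self._fasta = source._fasta
            self._seqs = source._seqs
            self._lengths = source._lengths
            return
        if isinstance(source, (str, Path)):
            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._seqs = None
            self._lengths = {name: len(rec) for name, rec in self._fasta.items()}
        else:
            self._fasta = None
            self._seqs = {k: str(v).upper() for k, v in source.items()}
            self._lengths = {k: len(v) for k, v in self._seqs.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        if chrom not in self._lengths:
            raise KeyError(f"contig {chrom!r} not present in genome")
        return self._lengths[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` on the forward strand, N-padded."""
        n = self.length(chrom)
        if end <= start:
            return ""
        lo, hi = max(start, 0), min(end, n)
        if hi <= lo:
            return "N" * (end - start)
        if self._fasta is not None:
            core = str(self._fasta[chrom][lo:hi])
        else:
            core = self._seqs[chrom][lo:hi]
        return "N" * (lo - start) + core + "N" * (end - hi)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS
    return df


def write_bed6(df: pd.DataFrame, path: str | Path, extra: Iterable[str] = ()) -> None:
    cols = BED6_COLUMNS + list(extra)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
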