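"""Independent brute-force oracles used to check the package's algorithms.

These deliberately take different computational routes from the library:
the motif oracle does per-position set membership over character tables
(the library uses bitmask intersection over sliding windows); the
clustering oracle merges seed pairs transitively in O(n^2) (the library
splits sorted gap runs).
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_CHAR_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def hamming_matches(seq: str, pattern: str, max_mismatch: int) -> list[int]:
    """Per-offset 0/1 matches by exhaustive Hamming scan (slow, per sequence)."""
    m = len(pattern)
    out = []
    for i in range(len(seq) - m + 1):
        mism = sum(1 for a, p in zip(seq[i : i + m], pattern) if a not in IUPAC_SETS[p])
        out.append(1 if mism <= max_mismatch else 0)
    return out


def encode_batch(seqs: list[str]) -> np.ndarray:
    """Equal-length sequences as an int matrix (A,C,G,T,N -> 0..4)."""
    return np.array([[_CHAR_TO_INT[c] for c in s] for s in seqs], dtype=np.int8)


def hamming_mismatch_batch(mat: np.ndarray, pattern: str) -> np.ndarray:
    """Exhaustive Hamming mismatch counts for every sequence and offset.

    For each pattern position a 5-entry membership table (A,C,G,T,N; N never
    matches) marks the allowed bases; mismatches are summed position by
    position over all offsets.
    """
    n_seq, L = mat.shape
    m = len(pattern)
    n_off = L - m + 1
    if n_off <= 0:
        return np.zeros((n_seq, 0), dtype=np.int16)
    out = np.zeros((n_seq, n_off), dtype=np.int16)
    for j, p in enumerate(pattern):
        allowed = np.array(
            [b in IUPAC_SETS[p] for b in "ACGT"] + [False], dtype=bool
        )
        out += ~allowed[mat[:, j : j + n_off]]
    return out


def bruteforce_distclu(
    positions: np.ndarray,
    pooled: np.ndarray,
    seed_mask: np.ndarray,
    max_dist: int,
    strand: str,
) -> list[dict]:
    """O(n^2) transitive merge of seed positions within ``max_dist``.

    Returns clusters as dicts with span, member positions (pooled signal > 0
    inside the seed span), dominant position (max pooled signal, ties to the
    5'-most position in transcript orientation) and total signal.
    """
    order = np.argsort(positions)
    positions = positions[order]
    pooled = pooled[order]
    seed_mask = seed_mask[order]
    seeds = [int(p) for p, s in zip(positions, seed_mask) if s]
    n = len(seeds)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(seeds[i] - seeds[j]) <= max_dist:
                a, b = find(i), find(j)
                if a != b:
                    parent[a] = b
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(seeds[i])
    clusters = []
    for members_seeds in groups.values():
        lo, hi = min(members_seeds), max(members_seeds)
        inside = (positions >= lo) & (positions <= hi) & (pooled > 0)
        mpos = positions[inside]
        msig = pooled[inside]
        best = msig.max()
        cand = mpos[msig == best]
        dom = int(cand.min() if strand == "+" else cand.max())
        clusters.append(
            {
                "start": int(lo),
                "end": int(hi) + 1,
                "members": set(int(p) for p in mpos),
                "dominant": dom,
                "total": float(msig.sum()),
            }
        )
    clusters.sort(key=lambda c: c["start"])
    return clusters
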