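"""Canonical k-mer counting, depth-histogram analysis, and genome-size estimation.

The estimator is the classical depth-distribution ratio: count canonical
k-mers in the reads, locate the error/signal valley of the depth histogram,
call every k-mer occurrence at or above that cutoff "error-free", and divide
the total number of error-free k-mer occurrences by the modal ("peak") depth:

    G_hat = sum_{d >= cutoff} d * n(d) / argmax_{d >= cutoff} n(d)

where n(d) is the number of distinct canonical k-mers seen exactly d times.
k is limited to 31 so each k-mer packs into a 62-bit integer code; counting
is exact (numpy `unique` over packed codes, vectorised across reads).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import encode_seq, round_half_up
from .formats_io import SeqRecord, read_table


@dataclass
class KmerHistogram:
    """Depth distribution: counts[d] = number of distinct canonical k-mers at depth d."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(d < 1 or n < 0 for d, n in self.counts.items()):
            raise ValueError("histogram depths must be >=1 and counts >=0")
        self.counts = {d: n for d, n in sorted(self.counts.items()) if n > 0}

    def total_distinct(self) -> int:
        return sum(self.counts.values())

    def total_occurrences(self) -> int:
        return sum(d * n for d, n in self.counts.items())

    def max_depth(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": list(self.counts), "count": list(self.counts.values())}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerHistogram":
        df = read_table(path, "kmer_hist")
        return cls(k=k, counts=dict(zip(df["depth"], df["count"])))


@dataclass
class GenomeSizeEstimate:
    k: int
    error_cutoff_depth: int
    cutoff_warning: bool
    peak_depth: int
    error_free_total: int
    size_bp: int

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "error_cutoff_depth": self.error_cutoff_depth,
            "cutoff_warning": self.cutoff_warning,
            "peak_depth": self.peak_depth,
            "error_free_total": self.error_free_total,
            "size_bp": self.size_bp,
        }


def _canonical_codes_matrix(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for a (n_reads, L) matrix of 2-bit base codes.

    Invalid bases (code 255, i.e. N) break the window: only windows made of
    k consecutive valid bases contribute.  Rolls forward and reverse codes
    simultaneously, one column at a time.
    """
    n, length = mat.shape
    if length < k:
        return np.empty(0, dtype=np.uint64)
    valid = mat != 255
    base = np.where(valid, mat, 0).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    two = np.uint64(2)
    three = np.uint64(3)
    hi_shift = np.uint64(2 * (k - 1))
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    runlen = np.zeros(n, dtype=np.int64)
    chunks: list[np.ndarray] = []
    for col in range(length):
        b = base[:, col]
        fwd = ((fwd << two) | b) & mask
        rev = (rev >> two) | ((three ^ b) << hi_shift)
        runlen = np.where(valid[:, col], runlen + 1, 0)
        if col >= k - 1:
            ok = runlen >= k
            if ok.any():
                chunks.append(np.minimum(fwd[ok], rev[ok]))
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(chunks)


def count_kmers(reads: Iterable[SeqRecord | str], k: int) -> KmerHistogram:
    """Count canonical k-mers across reads; exact depth histogram.

    Every length-k window free of N contributes the lexicographically smaller
    of itself and its reverse complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form is ill-defined for even k)")
    if not (1 <= k <= 31):
        raise ValueError("k must be within [1, 31]")
    by_length: dict[int, list[np.ndarray]] = defaultdict(list)
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        if len(seq) >= k:
            by_length[len(seq)].append(encode_seq(seq))
    all_codes: list[np.ndarray] = []
    for length, rows in by_length.items():
        mat = np.vstack(rows)
        codes = _canonical_codes_matrix(mat, k)
        if codes.size:
            all_codes.append(codes)
    if not all_codes:
        return KmerHistogram(k=k, counts={})
    _, occ = np.unique(np.concatenate(all_codes), return_counts=True)
    depths, ndistinct = np.unique(occ, return_counts=True)
    return KmerHistogram(k=k, counts={int(d): int(n) for d, n in zip(depths, ndistinct)})


def find_error_cutoff(hist: KmerHistogram) -> tuple[int, bool]:
    """Locate the error/signal valley of the depth histogram.

    Returns (cutoff_depth, warning).  The cutoff is the smallest depth d >= 2
    on the dense histogram (missing depths count 0) that is a local minimum
    (n(d) <= both neighbours) *and* separates positive mass on both sides —
    i.e. some shallower depth and some deeper depth both exceed n(d).  A
    unimodal histogram with no error tail has no such valley; then the cutoff
    falls back to 1 with warning=True.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    dmax = hist.max_depth()
    dense = np.zeros(dmax + 2, dtype=np.int64)  # index by depth; +1 slack for n(d+1)
    for d, n in hist.counts.items():
        dense[d] = n
    prefix_max = np.maximum.accumulate(dense[: dmax + 2])
    suffix_max = np.maximum.accumulate(dense[::-1])[::-1]
    for d in range(2, dmax + 1):
        nd = dense[d]
        if dense[d - 1] >= nd and dense[d + 1] >= nd:
            if prefix_max[d - 1] > nd and suffix_max[d + 1] > nd:
                return d, False
    return 1, True


def find_peak_depth(hist: KmerHistogram, cutoff: int) -> int:
    """Modal depth among k-mers at depth >= cutoff; ties go to the smaller depth."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    candidates = [(d, n) for d, n in hist.counts.items() if d >= cutoff]
    if not candidates:
        raise ValueError(f"no histogram mass at depth >= {cutoff}")
    best_d, best_n = candidates[0]
    for d, n in candidates[1:]:
        if n > best_n:
            best_d, best_n = d, n
    return best_d


def estimate_genome_size(hist: KmerHistogram, cutoff: int | None = None) -> GenomeSizeEstimate:
    """Ratio estimator: error-free k-mer occurrences divided by the peak depth."""
    if cutoff is None:
        cutoff, warning = find_error_cutoff(hist)
    else:
        warning = False
    peak = find_peak_depth(hist, cutoff)
    error_free_total = sum(d * n for d, n in hist.counts.items() if d >= cutoff)
    size_bp = int(round_half_up(error_free_total / peak))
    return GenomeSizeEstimate(
        k=hist.k,
        error_cutoff_depth=cutoff,
        cutoff_warning=warning,
        peak_depth=peak,
        error_free_total=error_free_total,
        size_bp=size_bp,
    )


def genome_coverage(assembly_total_bp: int, estimate_bp: int) -> float:
    """Assembly span as a percentage of the estimated genome size (one decimal)."""
    if assembly_total_bp <= 0 or estimate_bp <= 0:
        raise ValueError("assembly size and genome-size estimate must both be positive")
    return round_half_up(100.0 * assembly_total_bp / estimate_bp, 1)
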