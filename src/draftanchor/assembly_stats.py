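"""Assembly summary statistics: counts, lengths, N50, gap content, coverage.

Percentages and means are rounded half-up to the precision used in the
study's summary table (means to 2 decimals, percentages to 1).  N50 uses the
exact rational comparison 2*cumsum >= total, avoiding float ambiguity on odd
totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import round_half_up
from .formats_io import Assembly
from .kmer_size import genome_coverage


@dataclass
class AssemblyStats:
    num_sequences: int
    total_bp: int
    max_bp: int
    mean_bp: float
    n50_bp: int
    undefined_bases: int
    undefined_pct: float
    non_gapped_pct: float
    coverage_pct: float | None = None

    def as_dict(self) -> dict:
        return {
            "num_sequences": self.num_sequences,
            "total_bp": self.total_bp,
            "max_bp": self.max_bp,
            "mean_bp": self.mean_bp,
            "n50_bp": self.n50_bp,
            "undefined_bases": self.undefined_bases,
            "undefined_pct": self.undefined_pct,
            "non_gapped_pct": self.non_gapped_pct,
            "coverage_pct": self.coverage_pct,
        }


def n50(lengths: Iterable[int]) -> int:
    """Largest length L such that sequences of length >= L hold at least half
    of the total bases."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 of an empty length set is undefined")
    if any(l <= 0 for l in ls):
        raise ValueError("lengths must be positive")
    total = sum(ls)
    running = 0
    for l in ls:
        running += l
        if 2 * running >= total:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def mean_length(total_bp: int, num_sequences: int) -> float:
    """Mean sequence length rounded half-up to two decimals."""
    return round_half_up(total_bp / num_sequences, 2)


def undefined_pct(undefined_bases: int, total_bp: int) -> float:
    return round_half_up(100.0 * undefined_bases / total_bp, 1)


def non_gapped_pct(undefined_bases: int, total_bp: int) -> float:
    return round_half_up(100.0 * (total_bp - undefined_bases) / total_bp, 1)


def compute_stats(
    assembly: Assembly, genome_size_estimate: int | None = None
) -> AssemblyStats:
    """Full summary of an assembly; coverage only when an estimate is given."""
    if len(assembly) == 0:
        raise ValueError("assembly is empty")
    lengths = [len(r) for r in assembly]
    total = sum(lengths)
    undefined = sum(r.sequence.count("N") for r in assembly)
    return AssemblyStats(
        num_sequences=len(lengths),
        total_bp=total,
        max_bp=max(lengths),
        mean_bp=mean_length(total, len(lengths)),
        n50_bp=n50(lengths),
        undefined_bases=undefined,
        undefined_pct=undefined_pct(undefined, total),
        non_gapped_pct=non_gapped_pct(undefined, total),
        coverage_pct=(
            genome_coverage(total, genome_size_estimate)
            if genome_size_estimate
            else None
        ),
    )


def min_length_filter(assembly: Assembly, min_bp: int) -> tuple[Assembly, int]:
    """Drop sequences shorter than min_bp (boundary inclusive: >= min_bp kept)."""
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    kept = [r for r in assembly if len(r) >= min_bp]
    return Assembly(records=kept, name=assembly.name), len(assembly) - len(kept)
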