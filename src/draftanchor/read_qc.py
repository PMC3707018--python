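"""Read preprocessing: 3' quality trimming and length/quality-fraction filtering.

Two presets mirror the study's preprocessing regimes:

* DNA (whole-genome shotgun): trim 3' bases below Q30, then discard reads
  shorter than 50 bases or with fewer than 90% of bases at Q30 or better.
* RNA (transcriptome): trim below Q20, keep reads of at least 50 nucleotides
  with at least 75% of nucleotides at Q20 or more.

The quality-fraction rule is evaluated on the post-trim read (trimming is
listed first in the procedure).  Reads emptied by trimming count as "short".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .formats_io import SeqRecord


@dataclass(frozen=True)
class FilterPolicy:
    """Trim/filter thresholds. min_fraction of bases must be >= fraction_quality."""

    trim_quality: int
    min_length: int
    min_fraction: float
    fraction_quality: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be within [0, 1]")
        if min(self.trim_quality, self.min_length, self.fraction_quality) < 0:
            raise ValueError("thresholds must be non-negative")


#: Whole-genome shotgun preset: trim <Q30, keep len>=50 with >=90% bases >=Q30.
DNA_POLICY = FilterPolicy(trim_quality=30, min_length=50, min_fraction=0.90, fraction_quality=30)
#: Transcriptome preset: trim <Q20, keep len>=50 with >=75% bases >=Q20.
RNA_POLICY = FilterPolicy(trim_quality=20, min_length=50, min_fraction=0.75, fraction_quality=20)

POLICY_PRESETS = {"dna": DNA_POLICY, "rna": RNA_POLICY}


@dataclass
class QcSummary:
    reads_in: int = 0
    reads_kept: int = 0
    reads_discarded_short: int = 0
    reads_discarded_fraction: int = 0
    bases_trimmed: int = 0

    def check(self) -> None:
        assert self.reads_in == (
            self.reads_kept + self.reads_discarded_short + self.reads_discarded_fraction
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "reads_kept": self.reads_kept,
            "reads_discarded_short": self.reads_discarded_short,
            "reads_discarded_fraction": self.reads_discarded_fraction,
            "bases_trimmed": self.bases_trimmed,
        }


def trim_3prime(read: SeqRecord, threshold: int) -> SeqRecord:
    """Drop the 3' run of bases with quality below `threshold`.

    Returns the longest prefix whose final base has quality >= threshold; may
    be empty.  Idempotent.
    """
    if read.qualities is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    end = len(read.qualities)
    while end > 0 and read.qualities[end - 1] < threshold:
        end -= 1
    if end == len(read.qualities):
        return read
    return SeqRecord(id=read.id, sequence=read.sequence[:end], qualities=read.qualities[:end])


def apply_policy(read: SeqRecord, policy: FilterPolicy) -> tuple[bool, str, SeqRecord]:
    """Trim then test a read; returns (keep, reason, trimmed_read).

    reason is "kept", "short" or "fraction".
    """
    trimmed = trim_3prime(read, policy.trim_quality)
    n = len(trimmed)
    if n < policy.min_length:
        return False, "short", trimmed
    good = sum(1 for q in trimmed.qualities if q >= policy.fraction_quality)
    if good / n < policy.min_fraction:
        return False, "fraction", trimmed
    return True, "kept", trimmed


def run_qc(reads: Iterable[SeqRecord], policy: FilterPolicy) -> tuple[list[SeqRecord], QcSummary]:
    """Apply the policy to every read; kept reads returned in input order."""
    kept: list[SeqRecord] = []
    summary = QcSummary()
    for read in reads:
        summary.reads_in += 1
        keep, reason, trimmed = apply_policy(read, policy)
        summary.bases_trimmed += len(read) - len(trimmed)
        if keep:
            summary.reads_kept += 1
            kept.append(trimmed)
        elif reason == "short":
            summary.reads_discarded_short += 1
        else:
            summary.reads_discarded_fraction += 1
    summary.check()
    return kept, summary


def run_qc_paired(
    reads1: Iterable[SeqRecord],
    reads2: Iterable[SeqRecord],
    policy: FilterPolicy,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], list[SeqRecord], QcSummary]:
    """Paired mode: a pair survives only if both mates pass; single survivors
    become orphans (returned separately)."""
    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    orphans: list[SeqRecord] = []
    summary = QcSummary()
    for r1, r2 in zip(reads1, reads2, strict=True):
        summary.reads_in += 2
        k1, reason1, t1 = apply_policy(r1, policy)
        k2, reason2, t2 = apply_policy(r2, policy)
        summary.bases_trimmed += (len(r1) - len(t1)) + (len(r2) - len(t2))
        for keep, reason in ((k1, reason1), (k2, reason2)):
            if keep:
                summary.reads_kept += 1
            elif reason == "short":
                summary.reads_discarded_short += 1
            else:
                summary.reads_discarded_fraction += 1
        if k1 and k2:
            pairs.append((t1, t2))
        elif k1:
            orphans.append(t1)
        elif k2:
            orphans.append(t2)
    summary.check()
    return pairs, orphans, summary
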