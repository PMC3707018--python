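"""Exon-array probe placement and FPKM-sum quantification of genome regions.

Probes are kept only when they match the assembly perfectly and at exactly
one locus (forward or reverse-complement matches at distinct loci count as
distinct and make the probe non-unique).  Region expression is the sum of
FPKM values of transcripts overlapping the region by at least one base on
the same sequence, strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import Assembly, SeqRecord
from .superscaffold import occurrences


@dataclass(frozen=True)
class GenomeRegion:
    region_id: str
    seq_id: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


def regions_from_frame(df: pd.DataFrame) -> list[GenomeRegion]:
    return [
        GenomeRegion(region_id=str(r.region_id), seq_id=str(r.seq_id),
                     start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class ProbePlacement:
    probe_id: str
    seq_id: str
    start: int
    strand: str
    region_id: str | None
    partial_overlap: bool = False


def place_probes(
    probes: Iterable[SeqRecord],
    assembly: Assembly,
    regions: Sequence[GenomeRegion] = (),
) -> tuple[list[ProbePlacement], dict[str, str]]:
    """Retain probes with exactly one perfect match assembly-wide.

    Returns (placements, rejected) where rejected maps probe_id to the reason
    ("no_match" or "non_unique").  Retained placements are annotated with the
    region that fully contains them; a merely partial overlap annotates None
    and sets partial_overlap.
    """
    placements: list[ProbePlacement] = []
    rejected: dict[str, str] = {}
    for probe in probes:
        hits: list[tuple[str, int, str]] = []
        for rec in assembly:
            for off, strand, _mm in occurrences(probe.sequence, rec, max_mismatches=0):
                hits.append((rec.id, off, strand))
        if not hits:
            rejected[probe.id] = "no_match"
            continue
        if len(hits) > 1:
            rejected[probe.id] = "non_unique"
            continue
        seq_id, start, strand = hits[0]
        end = start + len(probe)
        region_id = None
        partial = False
        for region in regions:
            if region.seq_id != seq_id:
                continue
            if region.start <= start and end <= region.end:
                region_id = region.region_id
                break
            if start < region.end and end > region.start:
                partial = True
        placements.append(ProbePlacement(
            probe_id=probe.id, seq_id=seq_id, start=start, strand=strand,
            region_id=region_id, partial_overlap=partial and region_id is None,
        ))
    placements.sort(key=lambda p: p.probe_id)
    return placements, rejected


@dataclass(frozen=True)
class RegionExpression:
    region_id: str
    fpkm_sum: float
    n_transcripts: int


def sum_region_fpkm(region: GenomeRegion, transcripts: pd.DataFrame) -> RegionExpression:
    """Sum FPKM over transcripts overlapping the region by >= 1 bp.

    `transcripts` needs columns seq_id, start, end, fpkm (0-based half-open).
    """
    if (transcripts["fpkm"] < 0).any():
        bad = transcripts.loc[transcripts["fpkm"] < 0].iloc[0]
        raise ValueError(f"negative FPKM for transcript {bad.get('transcript_id', '?')}")
    hit = transcripts[
        (transcripts["seq_id"] == region.seq_id)
        & (transcripts["start"] < region.end)
        & (transcripts["end"] > region.start)
    ]
    return RegionExpression(
        region_id=region.region_id,
        fpkm_sum=float(hit["fpkm"].sum()),
        n_transcripts=int(len(hit)),
    )


def quantify_regions(
    regions: Sequence[GenomeRegion], transcripts: pd.DataFrame
) -> pd.DataFrame:
    """Region-expression table: region_id, fpkm_sum, n_transcripts."""
    rows = [sum_region_fpkm(r, transcripts) for r in regions]
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in rows],
            "fpkm_sum": [r.fpkm_sum for r in rows],
            "n_transcripts": [r.n_transcripts for r in rows],
        }
    )
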