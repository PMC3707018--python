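"""Physical-map-guided superscaffolding.

Sequence tags from a Whole Genome Profiling (WGP) style physical map are
located on the assembly; scaffolds carrying two or more tags of a single map
contig in fully concordant order are anchored and oriented; anchored
scaffolds are chained along each map contig into superscaffolds separated by
estimated N gaps.  Following the study's rules, any anchored sequence of
unknown orientation and any sequence spanning several map contigs is
discarded, and a superscaffold requires at least two unambiguously placed
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import encode_seq, revcomp
from .assembly_stats import n50
from .formats_io import Assembly, SeqRecord, read_table


# ---------------------------------------------------------------------------
# Physical map


@dataclass(frozen=True)
class MapTag:
    tag_id: str
    rank: int
    template_pos: int | None = None  # coordinate on the template genome, bp


@dataclass
class MapContig:
    id: str
    tags: list[MapTag]

    def __post_init__(self) -> None:
        ranks = [t.rank for t in self.tags]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(f"map contig {self.id!r}: tag ranks must strictly increase")


@dataclass
class PhysicalMap:
    contigs: list[MapContig]
    _tag_index: dict[str, tuple[str, MapTag]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tag_index = {}
        for contig in self.contigs:
            for tag in contig.tags:
                if tag.tag_id in self._tag_index:
                    raise ValueError(f"tag id {tag.tag_id!r} appears in more than one map contig")
                self._tag_index[tag.tag_id] = (contig.id, tag)

    def lookup(self, tag_id: str) -> tuple[str, MapTag]:
        return self._tag_index[tag_id]

    def __contains__(self, tag_id: str) -> bool:
        return tag_id in self._tag_index

    @classmethod
    def from_table(cls, path: str | Path) -> "PhysicalMap":
        """Build from a map_tags TSV (tag_id, map_contig_id, rank[, template_pos])."""
        df = read_table(path, "map_tags")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhysicalMap":
        contigs = []
        for cid, grp in df.groupby("map_contig_id", sort=True):
            grp = grp.sort_values("rank")
            tags = [
                MapTag(
                    tag_id=row.tag_id,
                    rank=int(row.rank),
                    template_pos=int(row.template_pos) if "template_pos" in df.columns else None,
                )
                for row in grp.itertuples()
            ]
            contigs.append(MapContig(id=str(cid), tags=tags))
        return cls(contigs=contigs)


# ---------------------------------------------------------------------------
# Tag placement


@dataclass(frozen=True)
class TagPlacement:
    tag_id: str
    scaffold_id: str
    offset: int  # 0-based start on the scaffold's forward strand
    strand: str  # "+" or "-"
    mismatches: int
    tag_length: int


def _find_exact(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def _find_with_mismatches(seq_codes: np.ndarray, pat_codes: np.ndarray, max_mm: int) -> np.ndarray:
    m = len(pat_codes)
    if len(seq_codes) < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, m)
    mism = (windows != pat_codes).sum(axis=1)  # N (code 255) never matches
    return np.nonzero(mism <= max_mm)[0]


def occurrences(
    pattern: str, record: SeqRecord, max_mismatches: int = 0
) -> list[tuple[int, str, int]]:
    """All (offset, strand, mismatches) placements of pattern on a scaffold.

    A palindromic pattern matching both strands at the same offset is
    reported once (forward).
    """
    rc = revcomp(pattern)
    out: list[tuple[int, str, int]] = []
    if max_mismatches == 0:
        seen: set[int] = set()
        for off in _find_exact(record.sequence, pattern):
            out.append((off, "+", 0))
            seen.add(off)
        for off in _find_exact(record.sequence, rc):
            if off not in seen:
                out.append((off, "-", 0))
    else:
        codes = encode_seq(record.sequence)
        pat = encode_seq(pattern).astype(codes.dtype)
        rcp = encode_seq(rc).astype(codes.dtype)
        fwd_hits = _find_with_mismatches(codes, pat, max_mismatches)
        rev_hits = _find_with_mismatches(codes, rcp, max_mismatches)
        fwd_set = set(int(o) for o in fwd_hits)
        for off in fwd_hits:
            mm = int((codes[off : off + len(pat)] != pat).sum())
            out.append((int(off), "+", mm))
        for off in rev_hits:
            if int(off) in fwd_set:
                continue
            mm = int((codes[off : off + len(rcp)] != rcp).sum())
            out.append((int(off), "-", mm))
    out.sort()
    return out


def place_tags(
    tags: Iterable[SeqRecord],
    assembly: Assembly,
    max_mismatches: int = 0,
) -> tuple[list[TagPlacement], list[str]]:
    """Place every tag on the assembly (both strands).

    Returns (unique_placements, non_unique_tag_ids): tags occurring more than
    once assembly-wide are flagged and excluded from anchoring.
    """
    placements: list[TagPlacement] = []
    non_unique: list[str] = []
    for tag in tags:
        hits: list[TagPlacement] = []
        for rec in assembly:
            for off, strand, mm in occurrences(tag.sequence, rec, max_mismatches):
                hits.append(TagPlacement(
                    tag_id=tag.id, scaffold_id=rec.id, offset=off,
                    strand=strand, mismatches=mm, tag_length=len(tag),
                ))
        if len(hits) == 1:
            placements.append(hits[0])
        elif len(hits) > 1:
            non_unique.append(tag.id)
    return placements, non_unique


# ---------------------------------------------------------------------------
# Anchoring


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    map_contig_id: str | None
    orientation: str  # "+", "-" or "unknown"
    anchor_rank: float | None
    status: str  # ok | unknown_orientation | multi_contig
    placements: list[TagPlacement] = field(default_factory=list)


def anchor_scaffolds(
    placements: Sequence[TagPlacement], pmap: PhysicalMap
) -> list[ScaffoldAnchor]:
    """Group unique tag placements per scaffold and infer map position/orientation.

    Orientation requires >=2 tags on one map contig with fully concordant
    (offset, rank) order: all ascending -> "+", all descending -> "-"; any
    discordance, a rank tie, or a single tag leaves the orientation unknown.
    Tags hitting more than one map contig mark the scaffold multi_contig.
    """
    by_scaffold: dict[str, list[TagPlacement]] = {}
    for pl in placements:
        if pl.tag_id not in pmap:
            raise KeyError(f"placement references unknown tag id {pl.tag_id!r}")
        by_scaffold.setdefault(pl.scaffold_id, []).append(pl)

    anchors: list[ScaffoldAnchor] = []
    for scaffold_id, pls in sorted(by_scaffold.items()):
        contig_ids = {pmap.lookup(pl.tag_id)[0] for pl in pls}
        if len(contig_ids) > 1:
            anchors.append(ScaffoldAnchor(
                scaffold_id=scaffold_id, map_contig_id=None,
                orientation="unknown", anchor_rank=None,
                status="multi_contig", placements=pls,
            ))
            continue
        contig_id = contig_ids.pop()
        ranked = sorted(
            ((pl.offset, pmap.lookup(pl.tag_id)[1].rank, pl) for pl in pls),
            key=lambda t: (t[0], t[1]),
        )
        ranks = [r for _, r, _ in ranked]
        mean_rank = sum(ranks) / len(ranks)
        if len(ranked) >= 2:
            ascending = all(b > a for a, b in zip(ranks, ranks[1:]))
            descending = all(b < a for a, b in zip(ranks, ranks[1:]))
        else:
            ascending = descending = False
        if ascending or descending:
            anchors.append(ScaffoldAnchor(
                scaffold_id=scaffold_id, map_contig_id=contig_id,
                orientation="+" if ascending else "-", anchor_rank=mean_rank,
                status="ok", placements=pls,
            ))
        else:
            anchors.append(ScaffoldAnchor(
                scaffold_id=scaffold_id, map_contig_id=contig_id,
                orientation="unknown", anchor_rank=mean_rank,
                status="unknown_orientation", placements=pls,
            ))
    return anchors


# ---------------------------------------------------------------------------
# Superscaffold construction


@dataclass(frozen=True)
class GapPolicy:
    """How inter-component gaps are sized.

    mode "template": gaps derive from tag template positions (projected
    component starts on the template genome), clamped to [min_gap, max_gap].
    mode "fixed": every gap is fixed_gap bp.
    """

    mode: str = "fixed"
    fixed_gap: int = 100
    min_gap: int = 10
    max_gap: int = 50_000

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "template"):
            raise ValueError(f"unknown gap policy mode {self.mode!r}")


@dataclass(frozen=True)
class SuperscaffoldComponent:
    scaffold_id: str
    orientation: str
    length_bp: int
    anchor_rank: float
    following_gap_bp: int | None  # None for the last component


@dataclass
class Superscaffold:
    id: str
    map_contig_id: str
    components: list[SuperscaffoldComponent]
    total_span_bp: int

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a superscaffold needs at least two components")
        ranks = [c.anchor_rank for c in self.components]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(f"superscaffold {self.id}: anchor ranks must strictly increase")


@dataclass
class SuperscaffoldReport:
    sequences_placed: int = 0
    discarded_unknown_orientation: int = 0
    discarded_multi_contig: int = 0
    unplaced_lt2_rule: int = 0
    n_superscaffolds: int = 0
    rank_ties_broken: int = 0
    gap_bases_added: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _projected_start(
    anchor: ScaffoldAnchor, scaffold_len: int, pmap: PhysicalMap
) -> float:
    """Estimate where the component's superscaffold-5' end sits on the template.

    For each tag, template_pos minus the distance from the component's leading
    end (in superscaffold orientation) to the tag start; averaged over tags.
    """
    estimates = []
    for pl in anchor.placements:
        tag = pmap.lookup(pl.tag_id)[1]
        if tag.template_pos is None:
            raise ValueError("template gap policy requires template_pos on map tags")
        if anchor.orientation == "+":
            lead = pl.offset
        else:
            lead = scaffold_len - pl.offset - pl.tag_length
        estimates.append(tag.template_pos - lead)
    return sum(estimates) / len(estimates)


def build_superscaffolds(
    anchors: Sequence[ScaffoldAnchor],
    pmap: PhysicalMap,
    gap_policy: GapPolicy,
    assembly: Assembly,
) -> tuple[list[Superscaffold], SuperscaffoldReport]:
    """Chain ok-anchored scaffolds per map contig into superscaffolds.

    Map contigs with fewer than two ok anchors yield nothing (their lone
    anchor is reported under the two-or-more rule).  Rank ties break by
    scaffold id and are flagged in the report.
    """
    report = SuperscaffoldReport()
    seen: set[str] = set()
    by_contig: dict[str, list[ScaffoldAnchor]] = {}
    for anchor in anchors:
        if anchor.status == "multi_contig":
            report.discarded_multi_contig += 1
            continue
        if anchor.status == "unknown_orientation":
            report.discarded_unknown_orientation += 1
            continue
        if anchor.scaffold_id in seen:
            raise RuntimeError(
                f"scaffold {anchor.scaffold_id!r} ok-anchored twice "
                f"(should have been multi_contig)"
            )
        seen.add(anchor.scaffold_id)
        by_contig.setdefault(anchor.map_contig_id, []).append(anchor)

    superscaffolds: list[Superscaffold] = []
    for contig_id in sorted(by_contig):
        group = by_contig[contig_id]
        if len(group) < 2:
            report.unplaced_lt2_rule += len(group)
            continue
        ranks_seen = [a.anchor_rank for a in group]
        if len(set(ranks_seen)) != len(ranks_seen):
            report.rank_ties_broken += len(ranks_seen) - len(set(ranks_seen))
        group.sort(key=lambda a: (a.anchor_rank, a.scaffold_id))

        lengths = [len(assembly[a.scaffold_id]) for a in group]
        if gap_policy.mode == "template":
            starts = [
                _projected_start(a, l, pmap) for a, l in zip(group, lengths)
            ]
            gaps = [
                int(min(max(round(s2 - (s1 + l1)), gap_policy.min_gap), gap_policy.max_gap))
                for s1, l1, s2 in zip(starts, lengths, starts[1:])
            ]
        else:
            gaps = [gap_policy.fixed_gap] * (len(group) - 1)

        components = [
            SuperscaffoldComponent(
                scaffold_id=a.scaffold_id,
                orientation=a.orientation,
                length_bp=l,
                anchor_rank=a.anchor_rank,
                following_gap_bp=(gaps[i] if i < len(gaps) else None),
            )
            for i, (a, l) in enumerate(zip(group, lengths))
        ]
        span = sum(lengths) + sum(gaps)
        superscaffolds.append(Superscaffold(
            id=f"ssc_{contig_id}",
            map_contig_id=contig_id,
            components=components,
            total_span_bp=span,
        ))
        report.sequences_placed += len(group)
        report.gap_bases_added += sum(gaps)
    report.n_superscaffolds = len(superscaffolds)
    return superscaffolds, report


def superscaffold_sequence(ssc: Superscaffold, assembly: Assembly) -> SeqRecord:
    """Render the gapped sequence of a superscaffold (gaps as runs of N)."""
    parts: list[str] = []
    for comp in ssc.components:
        seq = assembly[comp.scaffold_id].sequence
        parts.append(seq if comp.orientation == "+" else revcomp(seq))
        if comp.following_gap_bp is not None:
            parts.append("N" * comp.following_gap_bp)
    return SeqRecord(id=ssc.id, sequence="".join(parts))


def superscaffold_n50_gain(
    assembly: Assembly, superscaffolds: Sequence[Superscaffold]
) -> tuple[int, int]:
    """(n50_before, n50_after): superscaffold spans replace their components."""
    before = n50(len(r) for r in assembly)
    consumed = {c.scaffold_id for s in superscaffolds for c in s.components}
    after_lengths = [s.total_span_bp for s in superscaffolds]
    after_lengths += [len(r) for r in assembly if r.id not in consumed]
    return before, n50(after_lengths)
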