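"""In-silico PCR for SSR/COSII primer pairs and concordance aggregation.

A primer "site" is an ungapped, full-length placement of the primer (or its
reverse complement) at >= min_identity, identity = matches/primer_length; the
default 0.95 admits a single substitution on a 20-mer.  An amplicon arises
from a convergent site pair on the same sequence (one primer annealing to
each strand, facing inward) whose outer span does not exceed max_product_bp.
A marker is "unique" when exactly one amplicon exists genome-wide — the
retention rule used when anchoring markers to a draft assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import encode_seq, revcomp, round_half_up
from .formats_io import Assembly, SeqRecord


@dataclass(frozen=True)
class PrimerPair:
    marker_id: str
    forward_seq: str
    reverse_seq: str
    max_product_bp: int = 2000

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if len(seq) < 15:
                raise ValueError(f"{self.marker_id}: {name} primer shorter than 15 nt")
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"{self.marker_id}: {name} primer contains non-ACGT characters")
        object.__setattr__(self, "forward_seq", self.forward_seq.upper())
        object.__setattr__(self, "reverse_seq", self.reverse_seq.upper())
        if self.max_product_bp <= 0:
            raise ValueError("max_product_bp must be positive")


@dataclass(frozen=True)
class PrimerSite:
    seq_id: str
    start: int  # 0-based
    strand: str
    identity: float
    length: int


@dataclass(frozen=True)
class Amplicon:
    seq_id: str
    start: int  # 0-based half-open, outer primer boundaries
    end: int
    fwd_identity: float
    rev_identity: float

    @property
    def product_bp(self) -> int:
        return self.end - self.start


def find_primer_sites(
    primer: str, assembly: Assembly | Iterable[SeqRecord], min_identity: float = 0.95
) -> list[PrimerSite]:
    """Every ungapped full-length placement of the primer on either strand."""
    primer = primer.upper()
    m = len(primer)
    pat_f = encode_seq(primer)
    pat_r = encode_seq(revcomp(primer))
    sites: list[PrimerSite] = []
    for rec in assembly:
        codes = encode_seq(rec.sequence)
        if len(codes) < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, m)
        for pat, strand in ((pat_f, "+"), (pat_r, "-")):
            matches = m - (windows != pat).sum(axis=1)
            identity = matches / m
            for off in np.nonzero(identity >= min_identity - 1e-12)[0]:
                sites.append(PrimerSite(
                    seq_id=rec.id, start=int(off), strand=strand,
                    identity=float(identity[off]), length=m,
                ))
    return sites


def predict_amplicons(
    pair: PrimerPair,
    assembly: Assembly,
    min_identity: float = 0.95,
    max_product_bp: int | None = None,
) -> list[Amplicon]:
    """All convergent primer-site pairings within the product-size bound.

    Both primer roles are tried on both strands (the pair is unordered for
    convergence testing), so swapping forward and reverse primers leaves the
    result unchanged.  Site pairs whose span is shorter than the two primers
    (overlapping sites) are rejected.
    """
    limit = max_product_bp if max_product_bp is not None else pair.max_product_bp
    sites_f = find_primer_sites(pair.forward_seq, assembly, min_identity)
    sites_r = find_primer_sites(pair.reverse_seq, assembly, min_identity)
    amplicons: dict[tuple[str, int, int], Amplicon] = {}
    for left_sites, right_sites in ((sites_f, sites_r), (sites_r, sites_f)):
        for a in left_sites:
            if a.strand != "+":
                continue
            for b in right_sites:
                if b.strand != "-" or b.seq_id != a.seq_id:
                    continue
                if b.start < a.start + a.length:  # overlap or divergent
                    continue
                end = b.start + b.length
                if end - a.start > limit:
                    continue
                key = (a.seq_id, a.start, end)
                if key not in amplicons:
                    amplicons[key] = Amplicon(
                        seq_id=a.seq_id, start=a.start, end=end,
                        fwd_identity=a.identity, rev_identity=b.identity,
                    )
    return sorted(amplicons.values(), key=lambda x: (x.seq_id, x.start, x.end))


def classify_marker(
    pair: PrimerPair,
    assembly: Assembly,
    min_identity: float = 0.95,
    max_product_bp: int | None = None,
) -> str:
    """Genome-wide marker status: "unique", "multiple" or "none"."""
    n = len(predict_amplicons(pair, assembly, min_identity, max_product_bp))
    return "unique" if n == 1 else ("multiple" if n >= 2 else "none")


def classify_markers(
    pairs: Iterable[PrimerPair],
    assembly: Assembly,
    min_identity: float = 0.95,
    max_product_bp: int | None = None,
) -> dict[str, str]:
    return {
        p.marker_id: classify_marker(p, assembly, min_identity, max_product_bp)
        for p in pairs
    }


def pairs_from_frame(df: pd.DataFrame, max_product_bp: int = 2000) -> list[PrimerPair]:
    """Primer pairs from a primer_pairs table (marker_id, forward_seq, reverse_seq)."""
    return [
        PrimerPair(
            marker_id=str(r.marker_id),
            forward_seq=str(r.forward_seq),
            reverse_seq=str(r.reverse_seq),
            max_product_bp=max_product_bp,
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Concordance aggregation


def joint_category(status_a: str, status_b: str) -> str:
    """Two-genome joint mapping category; only "unique" counts as mapped."""
    a = status_a == "unique"
    b = status_b == "unique"
    if a and b:
        return "both"
    if a:
        return "A_only"
    if b:
        return "B_only"
    return "neither"


@dataclass
class ConcordanceTable:
    counts: pd.DataFrame  # evidence class x joint category
    warnings: list[str]

    def total(self, evidence_classes: Sequence[str] | None = None) -> int:
        df = self.counts
        if evidence_classes is not None:
            df = df.loc[[c for c in evidence_classes if c in df.index]]
        return int(df.to_numpy().sum())

    def mapped_to(self, genome: str, evidence_classes: Sequence[str] | None = None) -> int:
        """Markers mapped to genome "A" or "B": its exclusive category plus "both"."""
        df = self.counts
        if evidence_classes is not None:
            df = df.loc[[c for c in evidence_classes if c in df.index]]
        col = "A_only" if genome == "A" else "B_only"
        return int(df.get(col, pd.Series(0, index=df.index)).sum()
                   + df.get("both", pd.Series(0, index=df.index)).sum())

    def mapped_pct(self, genome: str, evidence_classes: Sequence[str] | None = None) -> int:
        total = self.total(evidence_classes)
        if total == 0:
            return 0
        return int(round_half_up(100.0 * self.mapped_to(genome, evidence_classes) / total))


_CATEGORIES = ["A_only", "B_only", "both", "neither"]


def aggregate_concordance(
    results_a: Mapping[str, str],
    results_b: Mapping[str, str],
    panel: Mapping[str, str],
) -> ConcordanceTable:
    """Cross-tabulate joint mapping category against external evidence class.

    `panel` assigns each marker its evidence class (e.g. which genetic map or
    amplification panel it belongs to).  Markers absent from the panel are
    tallied under "unknown" with a warning.
    """
    warnings: list[str] = []
    rows: dict[str, dict[str, int]] = {}
    for marker_id in sorted(set(results_a) | set(results_b)):
        sa = results_a.get(marker_id, "none")
        sb = results_b.get(marker_id, "none")
        cat = joint_category(sa, sb)
        cls = panel.get(marker_id)
        if cls is None:
            cls = "unknown"
            warnings.append(f"marker {marker_id!r} missing from panel")
        rows.setdefault(cls, {c: 0 for c in _CATEGORIES})[cat] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if counts.empty:
        counts = pd.DataFrame(columns=_CATEGORIES, dtype=int)
    else:
        counts = counts.reindex(columns=_CATEGORIES, fill_value=0).sort_index()
    return ConcordanceTable(counts=counts, warnings=warnings)
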