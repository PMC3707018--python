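"""Readers and writers for the on-disk formats the toolkit touches.

FASTA and FASTQ parsing is delegated to Biopython's low-level iterators; this
module adds the strict validation the pipeline relies on (restricted alphabet,
unique record ids, Phred+33 range checks) and the AGP v2.1 and TSV-table
dialects.  Internal coordinates are 0-based half-open everywhere; AGP converts
to 1-based inclusive on write.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import DNA_ALPHABET


class FormatError(ValueError):
    """Raised on any malformed input file."""


@dataclass
class SeqRecord:
    """A named DNA sequence, optionally with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )
            if any(q < 0 for q in self.qualities):
                raise FormatError(f"record {self.id!r}: negative Phred quality")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered set of scaffold/contig records with unique ids."""

    records: list[SeqRecord]
    name: str = "assembly"
    _index: dict[str, SeqRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.id in self._index:
                raise FormatError(f"duplicate sequence id: {rec.id!r}")
            self._index[rec.id] = rec

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SeqRecord:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def total_bp(self) -> int:
        return sum(len(r) for r in self.records)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an Assembly (order preserved, ids unique)."""
    path = Path(path)
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected '>' header, got {line[:30]!r}")
            break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = [
        SeqRecord(id=title.split()[0], sequence=seq)
        for title, seq in SimpleFastaParser(io.StringIO(text))
    ]
    return Assembly(records=records, name=name or path.stem)


def write_fasta(records: Iterable[SeqRecord] | Assembly, path: str | Path, width: int = 60) -> int:
    """Write records in normalized form (fixed line width); returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read Phred+33 FASTQ; qualities decoded to integer Phred scores."""
    path = Path(path)
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0]
                if len(seq) != len(qual):
                    raise FormatError(f"record {rid!r}: sequence/quality length mismatch")
                quals = [ord(c) - 33 for c in qual]
                if any(q < 0 or q > 93 for q in quals):
                    raise FormatError(f"record {rid!r}: quality character outside Phred+33 range")
                records.append(SeqRecord(id=rid, sequence=seq, qualities=quals))
        except ValueError as exc:  # Biopython signals truncation/mismatch as ValueError
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# AGP v2.1


@dataclass
class AgpRow:
    object_id: str
    object_start: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # "W" or "N"
    # W fields
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # N fields
    gap_length: int | None = None
    gap_type: str = "scaffold"
    evidence: str = "map"

    def to_line(self) -> str:
        if self.component_type == "W":
            cols = [
                self.object_id, str(self.object_start), str(self.object_end),
                str(self.part_number), "W", self.component_id,
                str(self.component_start), str(self.component_end), self.orientation,
            ]
        else:
            cols = [
                self.object_id, str(self.object_start), str(self.object_end),
                str(self.part_number), "N", str(self.gap_length),
                self.gap_type, "yes", self.evidence,
            ]
        return "\t".join(cols)


def superscaffold_agp_rows(superscaffold) -> list[AgpRow]:
    """Tile a superscaffold into alternating W/N AGP rows covering [1, span]."""
    rows: list[AgpRow] = []
    pos = 0  # 0-based cursor
    part = 1
    comps = superscaffold.components
    for i, comp in enumerate(comps):
        if comp.orientation not in ("+", "-"):
            raise FormatError(
                f"superscaffold {superscaffold.id}: component {comp.scaffold_id} "
                f"has no orientation"
            )
        rows.append(AgpRow(
            object_id=superscaffold.id,
            object_start=pos + 1,
            object_end=pos + comp.length_bp,
            part_number=part,
            component_type="W",
            component_id=comp.scaffold_id,
            component_start=1,
            component_end=comp.length_bp,
            orientation=comp.orientation,
        ))
        pos += comp.length_bp
        part += 1
        if i < len(comps) - 1:
            gap = comp.following_gap_bp
            if gap is None or gap <= 0:
                raise FormatError(
                    f"superscaffold {superscaffold.id}: missing gap after "
                    f"{comp.scaffold_id}"
                )
            rows.append(AgpRow(
                object_id=superscaffold.id,
                object_start=pos + 1,
                object_end=pos + gap,
                part_number=part,
                component_type="N",
                gap_length=gap,
            ))
            pos += gap
            part += 1
    return rows


def write_agp(superscaffolds: Sequence, path: str | Path) -> int:
    """Write superscaffolds as AGP v2.1; returns the number of rows written."""
    n = 0
    with _open_text(path, "wt") as fh:
        fh.write("##agp-version\t2.1\n")
        for ssc in superscaffolds:
            for row in superscaffold_agp_rows(ssc):
                fh.write(row.to_line() + "\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# TSV tables

TABLE_SCHEMAS: dict[str, dict[str, type]] = {
    "primer_pairs": {"marker_id": str, "forward_seq": str, "reverse_seq": str},
    "map_tags": {"tag_id": str, "map_contig_id": str, "rank": int},
    "fpkm": {"transcript_id": str, "seq_id": str, "start": int, "end": int, "fpkm": float},
    "regions": {"region_id": str, "seq_id": str, "start": int, "end": int},
    "kmer_hist": {"depth": int, "count": int},
}

# optional extra columns accepted per schema
_OPTIONAL_COLUMNS: dict[str, dict[str, type]] = {
    "map_tags": {"template_pos": int},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a tab-separated table and validate it against a named schema."""
    if schema not in TABLE_SCHEMAS:
        raise FormatError(f"unknown table schema: {schema!r}")
    columns = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: schema {schema!r} missing column(s): {missing}")
    optional = _OPTIONAL_COLUMNS.get(schema, {})
    for col, typ in list(columns.items()) + list(optional.items()):
        if col not in df.columns:
            continue
        if typ in (int, float):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise FormatError(
                    f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                    f"{col!r} at line {row}"
                )
            df[col] = converted.astype(int if typ is int else float)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
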