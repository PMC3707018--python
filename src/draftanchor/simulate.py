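"""Synthetic fixtures with recorded ground truth.

Generates, at desk scale, the kinds of inputs the pipeline was built for:
an i.i.d. random genome, shotgun reads with substitution errors and planted
QC failures, a fragmented shuffled assembly, a WGP-style tag map over the
genome, planted SSR-like primer pairs with known in-silico PCR status, and
probe/region/FPKM fixtures.  Everything is deterministic given the seed;
each operation draws from its own stream derived from (seed, operation
name), so adding operations never perturbs existing fixtures.

Genomes are i.i.d. (no repeat families): this keeps the k-mer depth
histogram unimodal, which is the regime the ratio size-estimator assumes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .formats_io import Assembly, SeqRecord
from .read_qc import DNA_POLICY, FilterPolicy
from .superscaffold import MapContig, MapTag, PhysicalMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale-down simulation parameters; seed is mandatory."""

    seed: int
    genome_bp: int = 100_000
    gc_fraction: float = 0.4
    n_scaffolds: int = 40
    read_length: int = 100
    coverage_x: float = 40.0
    error_rate: float = 0.005
    tag_length: int = 40
    tags_per_scaffold: int = 3
    n_map_contigs: int = 4
    n_markers: int = 50
    n_multiple_markers: int = 5
    n_absent_markers: int = 5
    n_one_mismatch_markers: int = 3
    qc_fail_short_frac: float = 0.0
    qc_fail_fraction_frac: float = 0.0
    probe_length: int = 25
    n_probes: int = 30
    n_probes_duplicated: int = 3
    n_probes_mutated: int = 3
    n_regions: int = 20
    n_transcripts: int = 60

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        for name in ("genome_bp", "n_scaffolds", "read_length", "tag_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Truth:
    """Ground truth recorded by the generator; consumed by recovery tests."""

    genome: str | None = None
    scaffolds: list[dict] = field(default_factory=list)  # genome order
    tags: list[dict] = field(default_factory=list)
    expected_anchor_status: dict[str, str] = field(default_factory=dict)
    expected_superscaffolds: dict[str, list[dict]] = field(default_factory=dict)
    markers: dict[str, dict] = field(default_factory=dict)
    qc_planted_short: list[str] = field(default_factory=list)
    qc_planted_fraction: list[str] = field(default_factory=list)
    probes: dict[str, dict] = field(default_factory=dict)
    region_fpkm: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _rng(config: SimConfig, op_name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(op_name.encode())])
    )


# ---------------------------------------------------------------------------
# Genome and reads


def simulate_genome(config: SimConfig) -> tuple[SeqRecord, Truth]:
    """i.i.d. genome at the configured GC content."""
    rng = _rng(config, "simulate_genome")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=config.genome_bp, p=probs)
    seq = _BASES[codes].tobytes().decode("ascii")
    truth = Truth(genome=seq)
    return SeqRecord(id="genome", sequence=seq), truth


def simulate_reads(
    genome: SeqRecord,
    config: SimConfig,
    policy: FilterPolicy = DNA_POLICY,
) -> tuple[list[SeqRecord], Truth]:
    """Uniform shotgun reads from both strands with i.i.d. substitution errors.

    Base quality is Q40, demoted to Q35 at error positions.  Planted QC
    failures override qualities deterministically: "short" reads get a 3'
    low-quality run leaving fewer than `policy.min_length` bases after
    trimming; "fraction" reads keep full length but push the share of bases
    at `policy.fraction_quality` or better below `policy.min_fraction`.
    """
    rng = _rng(config, "simulate_reads")
    genome_len = len(genome)
    read_len = config.read_length
    if read_len > genome_len:
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(config.coverage_x * genome_len / read_len))
    codes = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    code_map = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code_map[ord(b)] = i
    gcodes = code_map[codes]

    starts = rng.integers(0, genome_len - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    mat = gcodes[starts[:, None] + np.arange(read_len)[None, :]]
    rev_rows = np.nonzero(strands)[0]
    mat[rev_rows] = 3 - mat[rev_rows][:, ::-1]

    err_mask = rng.random((n_reads, read_len)) < config.error_rate
    n_err = int(err_mask.sum())
    if n_err:
        shifts = rng.integers(1, 4, size=n_err).astype(np.uint8)
        mat[err_mask] = (mat[err_mask] + shifts) % 4
    quals = np.full((n_reads, read_len), 40, dtype=np.int16)
    quals[err_mask] = 35

    truth = Truth()
    n_short = int(round(config.qc_fail_short_frac * n_reads))
    n_frac = int(round(config.qc_fail_fraction_frac * n_reads))
    if n_short + n_frac > 0:
        chosen = rng.choice(n_reads, size=n_short + n_frac, replace=False)
        low_trim = max(policy.trim_quality - 10, 2)
        low_frac = max(policy.fraction_quality - 10, 2)
        for idx in chosen[:n_short]:
            keep = int(rng.integers(5, policy.min_length))
            quals[idx, keep:] = low_trim
            quals[idx, keep - 1] = 40
            truth.qc_planted_short.append(f"read_{idx:07d}")
        n_low = read_len - int(np.ceil(read_len * policy.min_fraction)) + 1
        for idx in chosen[n_short:]:
            pos = rng.choice(read_len - 1, size=n_low, replace=False)
            quals[idx, pos] = low_frac
            quals[idx, read_len - 1] = 40
            truth.qc_planted_fraction.append(f"read_{idx:07d}")

    seq_bytes = _BASES[mat]
    reads = [
        SeqRecord(
            id=f"read_{i:07d}",
            sequence=seq_bytes[i].tobytes().decode("ascii"),
            qualities=quals[i].tolist(),
        )
        for i in range(n_reads)
    ]
    return reads, truth


# ---------------------------------------------------------------------------
# Fragmented assembly and WGP-style map


def fragment_assembly(genome: SeqRecord, config: SimConfig) -> tuple[Assembly, Truth]:
    """Cut the genome into n_scaffolds pieces, flip half, shuffle the ids.

    Truth records the genome order, coordinates and orientation of every
    piece; concatenating the truth-ordered, truth-oriented scaffolds
    reconstructs the genome exactly.
    """
    if config.n_scaffolds < 2:
        raise ValueError("need n_scaffolds >= 2")
    rng = _rng(config, "fragment_assembly")
    genome_len = len(genome)
    min_piece = max(2 * config.tag_length, 2)
    for _ in range(200):
        cuts = np.sort(rng.choice(np.arange(1, genome_len), size=config.n_scaffolds - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [genome_len]])
        pieces = np.diff(bounds)
        if pieces.min() >= min_piece:
            break
    else:
        raise ValueError("could not cut the genome into pieces of workable size")

    order = rng.permutation(config.n_scaffolds)
    flips = rng.random(config.n_scaffolds) < 0.5
    records: list[SeqRecord | None] = [None] * config.n_scaffolds
    truth = Truth()
    for piece_idx in range(config.n_scaffolds):
        start, end = int(bounds[piece_idx]), int(bounds[piece_idx + 1])
        sid = f"scf_{int(order[piece_idx]):04d}"
        seq = genome.sequence[start:end]
        orientation = "-" if flips[piece_idx] else "+"
        if orientation == "-":
            seq = revcomp(seq)
        records[int(order[piece_idx])] = SeqRecord(id=sid, sequence=seq)
        truth.scaffolds.append({
            "scaffold_id": sid, "orientation": orientation,
            "genome_start": start, "genome_end": end,
        })
    return Assembly(records=list(records), name="sim"), truth


def generate_wgp_map(
    genome: SeqRecord, truth: Truth, config: SimConfig
) -> tuple[PhysicalMap, list[SeqRecord]]:
    """Sample ordered sequence tags along the genome, grouped into map contigs.

    Tags are exact genome substrings, checked to be assembly-unique (exactly
    one occurrence counting both strands).  Map contigs partition the genome
    into n_map_contigs equal spans; ranks follow genome order within each
    contig and template_pos is the tag's genome coordinate.  Extends `truth`
    with per-scaffold expected anchoring outcomes.
    """
    rng = _rng(config, "generate_wgp_map")
    tlen = config.tag_length
    seq = genome.sequence
    genome_len = len(seq)
    if any(
        s["genome_end"] - s["genome_start"] <= tlen for s in truth.scaffolds
    ):
        raise ValueError("tag_length too large for the smallest scaffold")

    tag_entries: list[dict] = []  # genome order
    seen: set[str] = set()
    for scf in truth.scaffolds:
        lo, hi = scf["genome_start"], scf["genome_end"] - tlen
        span = hi - lo
        anchors = np.linspace(lo, hi, config.tags_per_scaffold + 2)[1:-1]
        for a in anchors:
            for _ in range(50):
                jitter = int(rng.integers(-span // (4 * config.tags_per_scaffold) - 1,
                                          span // (4 * config.tags_per_scaffold) + 2))
                pos = int(min(max(a + jitter, lo), hi))
                tag_seq = seq[pos : pos + tlen]
                rc = revcomp(tag_seq)
                if tag_seq in seen or rc in seen:
                    continue
                n_occ = seq.count(tag_seq) + (rc != tag_seq) * seq.count(rc)
                if n_occ == 1:
                    seen.add(tag_seq)
                    tag_entries.append({
                        "pos": pos, "seq": tag_seq, "scaffold_id": scf["scaffold_id"],
                    })
                    break
            else:
                raise ValueError("could not place a unique tag (infeasible spacing)")

    tag_entries.sort(key=lambda t: t["pos"])
    boundary = genome_len / config.n_map_contigs
    contigs: dict[str, list[MapTag]] = {}
    tag_records: list[SeqRecord] = []
    scaffold_contigs: dict[str, set[str]] = {}
    scaffold_tag_count: dict[str, int] = {}
    for i, entry in enumerate(tag_entries):
        tag_id = f"tag_{i:04d}"
        contig_idx = min(int(entry["pos"] // boundary), config.n_map_contigs - 1)
        contig_id = f"mapctg_{contig_idx:02d}"
        contigs.setdefault(contig_id, []).append(
            MapTag(tag_id=tag_id, rank=len(contigs.get(contig_id, [])),
                   template_pos=entry["pos"])
        )
        tag_records.append(SeqRecord(id=tag_id, sequence=entry["seq"]))
        truth.tags.append({
            "tag_id": tag_id, "pos": entry["pos"], "scaffold_id": entry["scaffold_id"],
            "map_contig_id": contig_id,
        })
        scaffold_contigs.setdefault(entry["scaffold_id"], set()).add(contig_id)
        scaffold_tag_count[entry["scaffold_id"]] = (
            scaffold_tag_count.get(entry["scaffold_id"], 0) + 1
        )

    # expected anchoring outcome per scaffold, mirroring the published rules
    orientation_of = {s["scaffold_id"]: s["orientation"] for s in truth.scaffolds}
    per_contig: dict[str, list[dict]] = {}
    for scf in truth.scaffolds:
        sid = scf["scaffold_id"]
        hit_contigs = scaffold_contigs.get(sid, set())
        if not hit_contigs:
            truth.expected_anchor_status[sid] = "unplaced"
        elif len(hit_contigs) > 1:
            truth.expected_anchor_status[sid] = "multi_contig"
        elif scaffold_tag_count[sid] < 2:
            truth.expected_anchor_status[sid] = "unknown_orientation"
        else:
            truth.expected_anchor_status[sid] = "ok"
            per_contig.setdefault(hit_contigs.pop(), []).append({
                "scaffold_id": sid, "orientation": orientation_of[sid],
                "genome_start": scf["genome_start"],
            })
    for contig_id, scfs in per_contig.items():
        scfs.sort(key=lambda s: s["genome_start"])
        if len(scfs) >= 2:
            truth.expected_superscaffolds[contig_id] = [
                {"scaffold_id": s["scaffold_id"], "orientation": s["orientation"]}
                for s in scfs
            ]
        else:
            truth.expected_anchor_status[scfs[0]["scaffold_id"]] = "unplaced_lt2"

    pmap = PhysicalMap(contigs=[
        MapContig(id=cid, tags=tags) for cid, tags in sorted(contigs.items())
    ])
    return pmap, tag_records


# ---------------------------------------------------------------------------
# Planted markers


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def plant_markers(
    genome: SeqRecord, config: SimConfig, primer_len: int = 20
) -> tuple[SeqRecord, pd.DataFrame, Truth]:
    """Plant primer pairs flanking 100-1,000 bp inserts in convergent orientation.

    Markers are laid out in disjoint slots (slot pitch exceeds the product
    cap, so no cross-slot amplicons can form).  A configurable subset is
    planted twice ("multiple"), another subset gets 2-substitution primers
    ("none"); a further subset gets one primer with a single substitution
    and remains "unique" at the 95% identity threshold.  Returns the
    (possibly rewritten) genome, the primer_pairs table and the truth.
    """
    rng = _rng(config, "plant_markers")
    n = config.n_markers
    n_multi = min(config.n_multiple_markers, n)
    n_absent = min(config.n_absent_markers, max(n - n_multi, 0))
    n_onemm = min(config.n_one_mismatch_markers, max(n - n_multi - n_absent, 0))
    n_slots = n + n_multi
    slot_w = len(genome) // max(n_slots, 1)
    if n and slot_w < primer_len * 2 + 1100:
        raise ValueError("genome too small for the requested number of markers")

    seq = list(genome.sequence)
    truth = Truth()
    rows = []
    statuses = (["multiple"] * n_multi + ["none"] * n_absent
                + ["unique"] * (n - n_multi - n_absent))
    rng.shuffle(statuses)
    onemm_pool = [i for i, s in enumerate(statuses) if s == "unique"][:n_onemm]
    extra_slot = n  # next free slot for second copies

    for i, status in enumerate(statuses):
        slot = i * slot_w
        insert = int(rng.integers(100, 1001))
        p = slot + int(rng.integers(0, slot_w - (2 * primer_len + insert)))
        q = p + primer_len + insert
        fwd = "".join(seq[p : p + primer_len])
        rsite = "".join(seq[q : q + primer_len])
        rev = revcomp(rsite)
        marker_id = f"mk_{i:03d}"
        planted = {"status": status, "sites": [[p, q + primer_len]]}
        if status == "multiple":
            slot2 = extra_slot * slot_w
            insert2 = int(rng.integers(100, 1001))
            p2 = slot2 + int(rng.integers(0, slot_w - (2 * primer_len + insert2)))
            q2 = p2 + primer_len + insert2
            seq[p2 : p2 + primer_len] = fwd
            seq[q2 : q2 + primer_len] = rsite
            planted["sites"].append([p2, q2 + primer_len])
            extra_slot += 1
        elif status == "none":
            fwd = _mutate(rng, fwd, 2)
            rev = _mutate(rng, rev, 2)
        elif i in onemm_pool:
            fwd = _mutate(rng, fwd, 1)
            planted["one_mismatch"] = True
        truth.markers[marker_id] = planted
        rows.append({"marker_id": marker_id, "forward_seq": fwd, "reverse_seq": rev})

    new_genome = SeqRecord(id=genome.id, sequence="".join(seq))
    table = pd.DataFrame(rows, columns=["marker_id", "forward_seq", "reverse_seq"])
    return new_genome, table, truth


# ---------------------------------------------------------------------------
# Probes, regions and expression


def plant_probes_and_expression(
    genome: SeqRecord, config: SimConfig
) -> tuple[SeqRecord, list[SeqRecord], pd.DataFrame, pd.DataFrame, Truth]:
    """Probe, region and FPKM fixtures with per-region true sums.

    Returns (genome, probes, regions_table, fpkm_table, truth).  Unique
    probes are exact genome substrings; a subset is copied to a second locus
    (non-unique) and another subset carries one substitution (imperfect, so
    rejected).  Transcript intervals get gamma-distributed FPKM; truth
    records each region's brute-force overlap sum.
    """
    rng = _rng(config, "plant_probes_and_expression")
    plen = config.probe_length
    n = config.n_probes
    n_dup = min(config.n_probes_duplicated, n)
    n_mut = min(config.n_probes_mutated, max(n - n_dup, 0))
    n_slots = n + n_dup
    slot_w = len(genome) // max(n_slots, 1)
    if n and slot_w < plen * 2:
        raise ValueError("genome too small for the requested number of probes")

    seq = list(genome.sequence)
    truth = Truth()
    kinds = ["duplicated"] * n_dup + ["mutated"] * n_mut + ["unique"] * (n - n_dup - n_mut)
    rng.shuffle(kinds)
    probes: list[SeqRecord] = []
    extra_slot = n
    for i, kind in enumerate(kinds):
        p = i * slot_w + int(rng.integers(0, slot_w - plen))
        probe_seq = "".join(seq[p : p + plen])
        entry = {"kind": kind, "pos": p}
        if kind == "duplicated":
            p2 = extra_slot * slot_w + int(rng.integers(0, slot_w - plen))
            seq[p2 : p2 + plen] = probe_seq
            entry["pos2"] = p2
            extra_slot += 1
        elif kind == "mutated":
            probe_seq = _mutate(rng, probe_seq, 1)
        pid = f"probe_{i:03d}"
        truth.probes[pid] = entry
        probes.append(SeqRecord(id=pid, sequence=probe_seq))
    new_genome = SeqRecord(id=genome.id, sequence="".join(seq))

    genome_len = len(new_genome)
    regions = []
    for i in range(config.n_regions):
        start = int(rng.integers(0, genome_len - 2000))
        regions.append({
            "region_id": f"rg_{i:03d}", "seq_id": new_genome.id,
            "start": start, "end": start + int(rng.integers(500, 2001)),
        })
    transcripts = []
    for i in range(config.n_transcripts):
        start = int(rng.integers(0, genome_len - 3000))
        transcripts.append({
            "transcript_id": f"tr_{i:03d}", "seq_id": new_genome.id,
            "start": start, "end": start + int(rng.integers(200, 3001)),
            "fpkm": float(np.round(rng.gamma(2.0, 5.0), 3)),
        })
    for rg in regions:  # brute-force truth
        total = 0.0
        for tr in transcripts:
            if tr["start"] < rg["end"] and tr["end"] > rg["start"]:
                total += tr["fpkm"]
        truth.region_fpkm[rg["region_id"]] = round(total, 6)

    return (
        new_genome,
        probes,
        pd.DataFrame(regions, columns=["region_id", "seq_id", "start", "end"]),
        pd.DataFrame(transcripts,
                     columns=["transcript_id", "seq_id", "start", "end", "fpkm"]),
        truth,
    )


# ---------------------------------------------------------------------------
# Presets


PRESETS: dict[str, dict] = {
    "gsize": dict(genome_bp=100_000, coverage_x=40.0, error_rate=0.005, read_length=100),
    "superscaffold": dict(genome_bp=1_000_000, n_scaffolds=40, n_map_contigs=4,
                          tag_length=40, tags_per_scaffold=3),
    "ispcr": dict(genome_bp=200_000, n_markers=50, n_multiple_markers=5,
                  n_absent_markers=5, n_one_mismatch_markers=3),
    "readqc": dict(genome_bp=25_000, coverage_x=40.0, read_length=100,
                   error_rate=0.002, qc_fail_short_frac=0.03,
                   qc_fail_fraction_frac=0.03),
    "probequant": dict(genome_bp=100_000, n_probes=30, n_probes_duplicated=3,
                       n_probes_mutated=3, n_regions=20, n_transcripts=60),
}


def preset_config(preset: str, seed: int, **overrides) -> SimConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    params = {**PRESETS[preset], **overrides}
    return SimConfig(seed=seed, **params)
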