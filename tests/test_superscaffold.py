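"""Tag placement, anchoring, and physical-map superscaffolding."""

import numpy as np
import pytest

from draftanchor._util import revcomp
from draftanchor.formats_io import Assembly, SeqRecord
from draftanchor.superscaffold import (
    GapPolicy,
    MapContig,
    MapTag,
    PhysicalMap,
    ScaffoldAnchor,
    TagPlacement,
    anchor_scaffolds,
    build_superscaffolds,
    place_tags,
    superscaffold_n50_gain,
    superscaffold_sequence,
)
from draftanchor import simulate as sim


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pmap(*contigs):
    return PhysicalMap(contigs=[
        MapContig(id=cid, tags=[MapTag(tag_id=t, rank=r) for r, t in enumerate(tags)])
        for cid, tags in contigs
    ])


class TestPlaceTags:
    def test_forward_planted(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 500)
        tag = seq[37:77]
        asm = Assembly([SeqRecord(id="S1", sequence=seq)])
        placements, flagged = place_tags([SeqRecord(id="t1", sequence=tag)], asm)
        assert flagged == []
        (pl,) = placements
        assert (pl.scaffold_id, pl.offset, pl.strand, pl.mismatches) == ("S1", 37, "+", 0)

    def test_reverse_strand_offset_convention(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 300)
        tag = revcomp(seq[100:140])  # tag matches the reverse strand
        asm = Assembly([SeqRecord(id="S1", sequence=seq)])
        (pl,), _ = place_tags([SeqRecord(id="t1", sequence=tag)], asm)
        assert (pl.offset, pl.strand) == (100, "-")

    def test_non_unique_tags_flagged(self):
        rng = np.random.default_rng(7)
        n_tags, n_dup = 200, 5
        pieces = [_random_seq(rng, 600) for _ in range(n_tags)]
        tags = []
        for i, piece in enumerate(pieces):
            tags.append(SeqRecord(id=f"t{i}", sequence=piece[10:50]))
        # plant 5 tags twice by reusing their substring in a second scaffold
        dup_seq = "".join(pieces[i][10:50] for i in range(n_dup))
        asm = Assembly(
            [SeqRecord(id=f"S{i}", sequence=p) for i, p in enumerate(pieces)]
            + [SeqRecord(id="Sdup", sequence=dup_seq)]
        )
        placements, flagged = place_tags(tags, asm)
        assert len(flagged) == n_dup
        assert sorted(flagged) == [f"t{i}" for i in range(n_dup)]
        assert len(placements) == n_tags - n_dup

    def test_mismatch_tolerance(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 400)
        tag = list(seq[50:90])
        tag[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[5]]
        asm = Assembly([SeqRecord(id="S1", sequence=seq)])
        exact, _ = place_tags([SeqRecord(id="t1", sequence="".join(tag))], asm)
        assert exact == []
        tol, _ = place_tags([SeqRecord(id="t1", sequence="".join(tag))], asm,
                            max_mismatches=1)
        assert len(tol) == 1 and tol[0].mismatches == 1


class TestAnchorScaffolds:
    def test_two_concordant_tags(self):
        pmap = _pmap(("C1", ["a", "b", "c", "d", "e", "f"]))
        placements = [
            TagPlacement("e", "S1", 10, "+", 0, 40),
            TagPlacement("f", "S1", 500, "+", 0, 40),
        ]
        (anchor,) = anchor_scaffolds(placements, pmap)
        assert anchor.status == "ok"
        assert anchor.orientation == "+"
        assert anchor.anchor_rank == 4.5

    def test_descending_ranks_give_minus(self):
        pmap = _pmap(("C1", ["a", "b", "c"]))
        placements = [
            TagPlacement("c", "S1", 10, "-", 0, 40),
            TagPlacement("a", "S1", 500, "-", 0, 40),
        ]
        (anchor,) = anchor_scaffolds(placements, pmap)
        assert anchor.orientation == "-" and anchor.status == "ok"

    def test_single_tag_unknown_orientation(self):
        pmap = _pmap(("C1", ["a"]))
        (anchor,) = anchor_scaffolds([TagPlacement("a", "S1", 5, "+", 0, 40)], pmap)
        assert anchor.status == "unknown_orientation"
        assert anchor.orientation == "unknown"

    def test_discordant_tags_unknown_orientation(self):
        pmap = _pmap(("C1", ["a", "b", "c"]))
        placements = [
            TagPlacement("a", "S1", 10, "+", 0, 40),
            TagPlacement("c", "S1", 200, "+", 0, 40),
            TagPlacement("b", "S1", 400, "+", 0, 40),
        ]
        (anchor,) = anchor_scaffolds(placements, pmap)
        assert anchor.status == "unknown_orientation"

    def test_multi_contig_discarded(self):
        pmap = _pmap(("C1", ["a"]), ("C2", ["b"]))
        placements = [
            TagPlacement("a", "S1", 10, "+", 0, 40),
            TagPlacement("b", "S1", 300, "+", 0, 40),
        ]
        (anchor,) = anchor_scaffolds(placements, pmap)
        assert anchor.status == "multi_contig"

    def test_unknown_tag_id_raises(self):
        pmap = _pmap(("C1", ["a"]))
        with pytest.raises(KeyError):
            anchor_scaffolds([TagPlacement("zz", "S1", 1, "+", 0, 40)], pmap)


class TestBuildSuperscaffolds:
    def _assembly(self, lengths):
        return Assembly([
            SeqRecord(id=sid, sequence="A" * n) for sid, n in lengths.items()
        ])

    def test_minimal_two_component(self):
        pmap = _pmap(("C1", ["a", "b", "c", "d", "e"]))
        anchors = [
            ScaffoldAnchor("S1", "C1", "+", 1.0, "ok"),
            ScaffoldAnchor("S2", "C1", "-", 4.0, "ok"),
        ]
        asm = self._assembly({"S1": 100, "S2": 80})
        sscs, report = build_superscaffolds(anchors, pmap, GapPolicy(), asm)
        (ssc,) = sscs
        assert [(c.scaffold_id, c.orientation) for c in ssc.components] == \
            [("S1", "+"), ("S2", "-")]
        assert ssc.total_span_bp == 100 + 100 + 80  # default fixed gap 100
        assert report.gap_bases_added == 100

    def test_single_anchor_yields_nothing(self):
        pmap = _pmap(("C1", ["a", "b"]))
        anchors = [ScaffoldAnchor("S1", "C1", "+", 1.0, "ok")]
        sscs, report = build_superscaffolds(anchors, pmap, GapPolicy(),
                                            self._assembly({"S1": 100}))
        assert sscs == [] and report.unplaced_lt2_rule == 1

    def test_duplicate_ok_scaffold_is_internal_error(self):
        pmap = _pmap(("C1", ["a"]), ("C2", ["b"]))
        anchors = [
            ScaffoldAnchor("S1", "C1", "+", 1.0, "ok"),
            ScaffoldAnchor("S1", "C2", "+", 1.0, "ok"),
        ]
        with pytest.raises(RuntimeError):
            build_superscaffolds(anchors, pmap, GapPolicy(), self._assembly({"S1": 10}))

    def test_gap_bases_equal_emitted_gaps(self, superscaffold_fixture):
        cfg, genome, assembly, pmap, tags, truth = superscaffold_fixture
        placements, _ = place_tags(tags, assembly)
        anchors = anchor_scaffolds(placements, pmap)
        sscs, report = build_superscaffolds(anchors, pmap, GapPolicy(mode="template"),
                                            assembly)
        emitted = sum(
            c.following_gap_bp for s in sscs for c in s.components
            if c.following_gap_bp is not None
        )
        assert report.gap_bases_added == emitted
        n_bases = sum(
            superscaffold_sequence(s, assembly).sequence.count("N") for s in sscs
        )
        assert n_bases == emitted  # i.i.d. sim genome itself contains no N


class TestEndToEndRecovery:
    def test_recovers_truth_order_and_orientation(self, superscaffold_fixture):
        cfg, genome, assembly, pmap, tags, truth = superscaffold_fixture
        placements, non_unique = place_tags(tags, assembly)
        assert non_unique == []
        anchors = anchor_scaffolds(placements, pmap)
        status_of = {a.scaffold_id: a.status for a in anchors}
        for sid, expected in truth.expected_anchor_status.items():
            if expected in ("unplaced", "unplaced_lt2"):
                continue
            assert status_of[sid] == expected, sid
        sscs, report = build_superscaffolds(anchors, pmap, GapPolicy(mode="template"),
                                            assembly)
        for ssc in sscs:
            expected = truth.expected_superscaffolds[ssc.map_contig_id]
            got = [
                {"scaffold_id": c.scaffold_id, "orientation": c.orientation}
                for c in ssc.components
            ]
            assert got == expected
        # partition: every scaffold accounted for exactly once
        consumed = {c.scaffold_id for s in sscs for c in s.components}
        n_accounted = (len(consumed) + report.discarded_unknown_orientation
                       + report.discarded_multi_contig + report.unplaced_lt2_rule)
        unanchored = sum(1 for r in assembly if r.id not in status_of)
        assert n_accounted + unanchored == len(assembly)

    def test_reversed_map_flips_orientations(self):
        cfg = sim.preset_config("superscaffold", seed=23, genome_bp=200_000,
                                n_scaffolds=10, n_map_contigs=1)
        genome, _ = sim.simulate_genome(cfg)
        assembly, truth = sim.fragment_assembly(genome, cfg)
        pmap, tags = sim.generate_wgp_map(genome, truth, cfg)
        placements, _ = place_tags(tags, assembly)
        forward = build_superscaffolds(
            anchor_scaffolds(placements, pmap), pmap, GapPolicy(), assembly)[0]
        # reverse the tag order of every map contig
        reversed_contigs = [
            MapContig(id=c.id, tags=[
                MapTag(tag_id=t.tag_id, rank=i, template_pos=t.template_pos)
                for i, t in enumerate(reversed(c.tags))
            ])
            for c in pmap.contigs
        ]
        rev_map = PhysicalMap(contigs=reversed_contigs)
        reverse = build_superscaffolds(
            anchor_scaffolds(placements, rev_map), rev_map, GapPolicy(), assembly)[0]
        flip = {"+": "-", "-": "+"}
        for f, r in zip(forward, reverse):
            f_comps = [(c.scaffold_id, c.orientation) for c in f.components]
            r_comps = [(c.scaffold_id, flip[c.orientation]) for c in reversed(r.components)]
            assert f_comps == r_comps

    def test_one_tag_per_scaffold_yields_no_superscaffolds(self):
        cfg = sim.preset_config("superscaffold", seed=11, genome_bp=200_000,
                                n_scaffolds=10, tags_per_scaffold=1)
        genome, _ = sim.simulate_genome(cfg)
        assembly, truth = sim.fragment_assembly(genome, cfg)
        pmap, tags = sim.generate_wgp_map(genome, truth, cfg)
        placements, _ = place_tags(tags, assembly)
        anchors = anchor_scaffolds(placements, pmap)
        sscs, report = build_superscaffolds(anchors, pmap, GapPolicy(), assembly)
        assert sscs == []
        assert report.discarded_unknown_orientation == len(anchors)


def test_n50_gain_bookkeeping(superscaffold_fixture):
    cfg, genome, assembly, pmap, tags, truth = superscaffold_fixture
    placements, _ = place_tags(tags, assembly)
    anchors = anchor_scaffolds(placements, pmap)
    sscs, _ = build_superscaffolds(anchors, pmap, GapPolicy(mode="template"), assembly)
    before, after = superscaffold_n50_gain(assembly, sscs)
    assert after >= before  # joining can only help
    before2, after2 = superscaffold_n50_gain(assembly, [])
    assert before2 == after2
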