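"""In-silico PCR: site finding, amplicon prediction, status and concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from draftanchor._util import revcomp
from draftanchor.formats_io import Assembly, SeqRecord
from draftanchor.marker_ispcr import (
    PrimerPair,
    aggregate_concordance,
    classify_marker,
    classify_markers,
    find_primer_sites,
    joint_category,
    pairs_from_frame,
    predict_amplicons,
)
from draftanchor import simulate as sim


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_sites(primer, assembly, min_identity):
    """Sliding-window Hamming scan on both strands, pure python."""
    out = []
    m = len(primer)
    for rec in assembly:
        seq = rec.sequence
        for pat, strand in ((primer, "+"), (revcomp(primer), "-")):
            for i in range(len(seq) - m + 1):
                matches = sum(a == b for a, b in zip(seq[i : i + m], pat))
                if matches / m >= min_identity - 1e-12:
                    out.append((rec.id, i, strand))
    return sorted(out)


def brute_force_amplicons(pair, assembly, min_identity, max_product):
    sites_f = brute_force_sites(pair.forward_seq, assembly, min_identity)
    sites_r = brute_force_sites(pair.reverse_seq, assembly, min_identity)
    lf, lr = len(pair.forward_seq), len(pair.reverse_seq)
    amps = set()
    for left, llen, right, rlen in ((sites_f, lf, sites_r, lr),
                                    (sites_r, lr, sites_f, lf)):
        for sid_a, a, strand_a in left:
            if strand_a != "+":
                continue
            for sid_b, b, strand_b in right:
                if strand_b != "-" or sid_b != sid_a:
                    continue
                if b < a + llen:
                    continue
                if b + rlen - a > max_product:
                    continue
                amps.add((sid_a, a, b + rlen))
    return sorted(amps)


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestFindPrimerSites:
    def test_exact_planted(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 2000)
        primer = seq[500:520]
        asm = Assembly([SeqRecord(id="g", sequence=seq)])
        sites = find_primer_sites(primer, asm)
        exact = [s for s in sites if s.identity == 1.0 and s.strand == "+"]
        assert any(s.start == 500 for s in exact)

    def test_identity_boundary_one_vs_two_mismatches(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 5000)
        primer = seq[1000:1020]
        asm = Assembly([SeqRecord(id="g", sequence=seq)])
        one_mm = _mutate(primer, [3])
        sites = [s for s in find_primer_sites(one_mm, asm) if s.start == 1000]
        assert len(sites) == 1 and sites[0].identity == pytest.approx(0.95)
        two_mm = _mutate(primer, [3, 11])
        assert [s for s in find_primer_sites(two_mm, asm) if s.start == 1000] == []

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 100_000)
        asm = Assembly([SeqRecord(id="g", sequence=seq)])
        for trial in range(3):
            primer = _random_seq(rng, 16)  # short primer -> plausible near-matches
            got = sorted(
                (s.seq_id, s.start, s.strand)
                for s in find_primer_sites(primer, asm, min_identity=0.85)
            )
            assert got == brute_force_sites(primer, asm, 0.85)


class TestPredictAmplicons:
    def _planted_assembly(self, rng, insert=300):
        seq = _random_seq(rng, 5000)
        fwd = seq[1000:1020]
        rsite_start = 1020 + insert
        rev = revcomp(seq[rsite_start : rsite_start + 20])
        return Assembly([SeqRecord(id="g", sequence=seq)]), fwd, rev

    def test_convergent_pair_product_size(self):
        rng = np.random.default_rng(4)
        asm, fwd, rev = self._planted_assembly(rng, insert=300)
        pair = PrimerPair("m1", fwd, rev)
        amps = [a for a in predict_amplicons(pair, asm) if a.start == 1000]
        assert len(amps) == 1
        assert amps[0].product_bp == 300 + 20 + 20  # insert plus both primers

    def test_divergent_orientation_rejected(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 5000)
        # primers point away from each other: reverse-site upstream of forward
        fwd = seq[2000:2020]
        rev = revcomp(seq[1000:1020])
        asm = Assembly([SeqRecord(id="g", sequence=seq)])
        pair = PrimerPair("m1", fwd, rev)
        assert [a for a in predict_amplicons(pair, asm)
                if 1000 <= a.start <= 2020] == []

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        asm, fwd, rev = self._planted_assembly(rng)
        a1 = predict_amplicons(PrimerPair("m", fwd, rev), asm)
        a2 = predict_amplicons(PrimerPair("m", rev, fwd), asm)
        assert [(a.seq_id, a.start, a.end) for a in a1] == \
            [(a.seq_id, a.start, a.end) for a in a2]

    def test_max_product_cap(self):
        rng = np.random.default_rng(7)
        asm, fwd, rev = self._planted_assembly(rng, insert=1500)
        assert predict_amplicons(PrimerPair("m", fwd, rev), asm,
                                 max_product_bp=1000) == []
        assert len(predict_amplicons(PrimerPair("m", fwd, rev), asm,
                                     max_product_bp=2000)) >= 1


class TestClassifyMarkers:
    def test_planted_truth_recovered(self, ispcr_fixture):
        cfg, asm, table, truth = ispcr_fixture
        statuses = classify_markers(pairs_from_frame(table), asm)
        assert len(statuses) == cfg.n_markers
        for marker_id, status in statuses.items():
            assert status == truth.markers[marker_id]["status"], marker_id
        # partition invariant
        from collections import Counter
        counts = Counter(statuses.values())
        assert sum(counts.values()) == cfg.n_markers
        assert counts["multiple"] == cfg.n_multiple_markers
        assert counts["none"] == cfg.n_absent_markers

    def test_one_mismatch_markers_stay_unique(self, ispcr_fixture):
        cfg, asm, table, truth = ispcr_fixture
        onemm = [m for m, e in truth.markers.items() if e.get("one_mismatch")]
        assert len(onemm) == cfg.n_one_mismatch_markers
        statuses = classify_markers(
            pairs_from_frame(table[table.marker_id.isin(onemm)]), asm)
        assert all(s == "unique" for s in statuses.values())

    def test_full_pipeline_matches_bruteforce(self, ispcr_fixture):
        cfg, asm, table, truth = ispcr_fixture
        sub = table.head(10)
        for pair in pairs_from_frame(sub):
            got = [(a.seq_id, a.start, a.end)
                   for a in predict_amplicons(pair, asm)]
            assert got == brute_force_amplicons(pair, asm, 0.95, 2000)


class TestConcordance:
    def test_joint_category_rule(self):
        assert joint_category("unique", "unique") == "both"
        assert joint_category("unique", "multiple") == "A_only"
        assert joint_category("none", "unique") == "B_only"
        assert joint_category("multiple", "none") == "neither"

    def test_published_map_aggregation(self):
        """75 + 50 + 1 + 2 markers mapped to genome A out of a 173-marker map."""
        results_a, results_b, panel = {}, {}, {}
        idx = 0

        def add(n, cls, sa, sb):
            nonlocal idx
            for _ in range(n):
                mid = f"m{idx:03d}"
                panel[mid] = cls
                results_a[mid] = sa
                results_b[mid] = sb
                idx += 1

        add(75, "map_A", "unique", "none")       # found in A only
        add(50, "map_A", "unique", "unique")     # found in both
        add(1, "map_A_and_B", "unique", "none")  # shared-map marker, A only
        add(2, "map_A_and_B", "unique", "unique")
        add(45, "map_A", "none", "none")         # the rest of the 173 not mapped
        table = aggregate_concordance(results_a, results_b, panel)
        classes = ["map_A", "map_A_and_B"]
        assert table.total(classes) == 173
        assert table.mapped_to("A", classes) == 128
        assert table.mapped_pct("A", classes) == 74

    def test_empty_results(self):
        table = aggregate_concordance({}, {}, {})
        assert table.total() == 0 and table.mapped_to("A") == 0

    def test_unknown_marker_warns(self):
        table = aggregate_concordance({"m1": "unique"}, {"m1": "none"}, {})
        assert table.counts.loc["unknown", "A_only"] == 1
        assert table.warnings

    def test_simulated_panel_matches_generator_truth(self, ispcr_fixture):
        cfg, asm, table, truth = ispcr_fixture
        statuses = classify_markers(pairs_from_frame(table), asm)
        panel = {m: "panel_sim" for m in statuses}
        # genome B: nothing maps (different species stand-in)
        results_b = {m: "none" for m in statuses}
        ct = aggregate_concordance(statuses, results_b, panel)
        expected_a_only = sum(
            1 for e in truth.markers.values() if e["status"] == "unique")
        assert ct.mapped_to("A") == expected_a_only
        assert ct.total() == cfg.n_markers


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair("m", "ACGT", "ACGTACGTACGTACGTACGT")
    with pytest.raises(ValueError):
        PrimerPair("m", "ACGTNACGTACGTACGTACG", "ACGTACGTACGTACGTACGT")
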