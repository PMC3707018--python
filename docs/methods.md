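# Methods

This note documents the models, rules and numerical choices behind
draftanchor, and what the synthetic fixtures do and do not establish about
real data.

## k-mer genome-size estimation

The estimator assumes reads are drawn roughly uniformly from a genome at
coverage high enough that genuine genomic k-mers form a clear depth peak,
while sequencing errors create mostly novel k-mers at depth 1–2. With n(d)
the number of distinct canonical k-mers at depth d, the size estimate is
Σ_{d≥c} d·n(d) / p, where c is the error cutoff and p the modal depth above
it.

Choices:

* **Canonical k-mers.** Each window is collapsed with its reverse
  complement (lexicographic minimum). This makes the histogram invariant
  under reverse-complementing the reads, which is also a property test.
  k is odd (a k-mer can then never equal its own reverse complement) and
  ≤ 31 so a k-mer packs into a 62-bit integer; counting is exact, done with
  numpy over packed codes.
* **Error cutoff.** c is the smallest depth d ≥ 2 on the dense histogram
  that is a local minimum *and* separates positive mass on both sides (some
  shallower and some deeper depth both exceed n(d)). The side condition
  matters: without it, any zero-filled gap in a sparse histogram — or the
  flat region below an error-free coverage peak — would qualify, which is
  clearly not a valley between an error tail and a signal peak. A unimodal
  histogram with no error tail has no valley; the cutoff then falls back to
  1 with a warning flag.
* **Peak depth.** Argmax of n(d) over d ≥ c; ties break toward the smaller
  depth for determinism. No smoothing is applied.
* **N handling.** Windows containing N contribute nothing.

Accuracy at desk scale: on simulated 100 kb genomes at 40× with 0.5% error,
the median absolute error over ten seeds is well under 5%. The dominant
error term is discretization of the peak: expected per-k-mer coverage is
C·(L−k+1)/L ≈ 28 for C = 40×, L = 100, k = 31, so a one-unit shift of the
mode moves the estimate by ~3.6%. Real genomes add heterozygosity and
repeats, which this simple ratio estimator does not model (no
mixture/model-fitting of the histogram); the i.i.d. simulated genomes are
deliberately in the regime the estimator assumes.

## Read preprocessing

Two policy presets: DNA (trim < Q30, keep length ≥ 50 with ≥ 90% of bases
≥ Q30) and RNA (trim < Q20, keep length ≥ 50 with ≥ 75% ≥ Q20). The
quality-fraction rule is evaluated on the post-trim read, because trimming
is the first step of the procedure; an empty post-trim read counts as
"short". The three outcomes (kept / short / fraction) partition the input,
and trimming is idempotent — both are property-tested. In paired mode a
pair survives only if both mates pass; lone survivors are emitted as
orphans, the convention assemblers expect.

## Assembly statistics

N50 uses the exact integer comparison 2·(running sum) ≥ total on lengths
sorted descending, avoiding float ambiguity for odd totals; it is invariant
under permutation and duplication of the length multiset. Means are rounded
half-up to 2 decimals and percentages to 1, matching the precision of
published assembly tables; lowercase bases are uppercased on read, so 'n'
counts as undefined. The minimum-length filter (default threshold 200 bp
when invoked) is boundary-inclusive.

## Physical-map superscaffolding

Tag placement is exact-match by default; WGP-style tags derive from the
same species' sequence, so no mismatch tolerance is assumed (a tolerance
flag exists). A tag occurring more than once assembly-wide is flagged
non-unique and excluded from anchoring. A palindromic tag matching both
strands at the same locus counts once.

Anchoring demands full pairwise concordance: with placements sorted by
scaffold offset, map ranks must be strictly increasing (orientation +) or
strictly decreasing (−); any discordance, rank tie, or a single tag leaves
the orientation unknown. There is no majority voting — "oriented
unambiguously" is taken literally. Scaffolds whose tags hit several map
contigs are set aside as multi-contig. Per map contig, ok-anchored
scaffolds are ordered by mean tag rank (ties broken by scaffold id and
flagged); two or more are required to emit a superscaffold.

Gap lengths: with a template genome available (tags carry template
coordinates), each component's leading edge is projected onto the template
from its tags (template position minus the scaffold-coordinate distance
from the component's leading end, averaged over tags), and the gap is the
projected inter-component distance clamped to [10 bp, 50 kb]. The clamp
keeps AGP output valid when tag noise would imply negative or absurd gaps.
Without a template, gaps are a fixed 100 bp. These are design choices — the
estimation-from-template idea mirrors how such gaps are sized in practice,
but no published formula exists for it.

Internally all coordinates are 0-based half-open; AGP v2.1 output converts
to 1-based inclusive, with N rows typed `scaffold` / evidence `map`. AGP
rows provably tile each object exactly (property test).

## In-silico PCR

Primer matching is ungapped, full-length, substitutions only: at the 95%
identity threshold an 18–24-mer admits at most one substitution, and indel
handling in the original alignment tooling is unspecified, so modelling
substitutions only keeps the rule sharp and testable. Identity is applied
per primer; both primers must pass. Amplicons require convergent
orientation on the same sequence (one primer on each strand, facing
inward), a span of at least the two primer lengths (overlapping sites are
rejected), and at most `max_product_bp` (default 2,000 — SSR/COSII products
are short; the original size cap is unstated). Both primer roles are tried
on both strands, so the pair is unordered and forward/reverse swap is a
symmetry (tested). Marker status is unique / multiple / none by genome-wide
amplicon count; only unique markers are retained for anchoring.
Concordance tables cross-tabulate joint status (A_only / B_only / both /
neither) against panel evidence classes; percentages round half-up to whole
numbers as in published marker tables.

## Probe placement and region FPKM

A probe is retained only on a perfect, genome-wide-unique match; a forward
match at one locus and a reverse-complement match at another are two
matches and disqualify the probe. Region annotation requires full
containment; partial overlap is flagged but annotates none. Region
expression sums FPKM of transcripts overlapping the region by ≥ 1 bp on
the same sequence, strand-agnostic (no strandedness is specified for the
procedure) and using transcript spans rather than exon structure. Negative
FPKM is rejected as a data error.

## Synthetic fixtures

The generator produces i.i.d. genomes (default GC 0.4), uniform shotgun
reads with i.i.d. substitution errors (default 0.5%, read length 100 bp,
coverage 40×), fragmented shuffled assemblies, tag maps, planted markers
and probes, and FPKM tables — all deterministic given the seed, with one
RNG stream per operation derived from (seed, operation name) so adding an
operation never perturbs existing fixtures. Problem sizes used throughout
the tests — 100 kb genomes for size estimation, a 1 Mb genome in 40
scaffolds with a 4-contig map for superscaffolding, 200 kb with 50 markers
for in-silico PCR, 10,000 reads for QC — are chosen so every suite
exercises the full algorithms while brute-force oracles remain feasible.

What the fixtures do *not* model: repeat families, heterozygosity,
quality-by-cycle error profiles, indels, and mate-pair structure. Passing
recovery tests therefore demonstrates the correctness of the anchoring,
classification and estimation logic under the stated assumptions, not
robustness to repeat-rich plant genomes — where, for instance, tag and
primer uniqueness filters will discard far more input, exactly as the
published marker-mapping rates reflect.

QC-failure planting writes qualities that violate exactly one rule: "short"
reads get a 3'-run below the trim threshold leaving fewer than the minimum
bases, "fraction" reads keep full length but drop just below the required
good-base share (interior positions only, so trimming is not triggered).
Erroneous bases get slightly lower quality (Q35 vs Q40) but stay above the
thresholds, so planted counts are exact ground truth.

## Degenerate inputs and tie-breaks

Empty histograms, empty assemblies, and empty length sets raise; an
all-below-threshold read trims to empty and is discarded as short; peak and
rank ties break toward the smaller value / lexicographic id; percentages
and means round half-up (ties away from zero) everywhere, via decimal
arithmetic rather than binary-float rounding.
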