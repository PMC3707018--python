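"""Summary statistics of a (synthetic) draft assembly.

Reports the figures a draft-genome paper tabulates: sequence count, total
and mean length, N50, undefined-base (N) content, and coverage of an
independently estimated genome size.
"""

from draftanchor import simulate as sim
from draftanchor.assembly_stats import compute_stats

cfg = sim.preset_config("superscaffold", seed=11, genome_bp=500_000)
genome, _ = sim.simulate_genome(cfg)
assembly, _ = sim.fragment_assembly(genome, cfg)

stats = compute_stats(assembly, genome_size_estimate=600_000)

print(f"sequences      : {stats.num_sequences:,}")
print(f"total length   : {stats.total_bp:,} bp")
print(f"mean length    : {stats.mean_bp:,.2f} bp")
print(f"N50            : {stats.n50_bp:,} bp")
print(f"undefined bases: {stats.undefined_bases:,} ({stats.undefined_pct}%)")
print(f"non-gapped     : {stats.non_gapped_pct}%")
print(f"genome coverage: {stats.coverage_pct}%")
# N50 is the largest length L such that sequences of length >= L hold at
# least half the assembly; coverage is assembly span over the estimated
# genome size (here 500 kb over a pretend 600 kb estimate = 83.3%).
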