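"""Gabriel haplotype blocks and the marker-density recommendation.

Plants a four-marker complete-LD block inside an otherwise independent
12-marker chromosome, recovers it from |D'| confidence intervals, and
derives the marker count a genome of a given size would need at the
within-block spacing.
"""

from ldscape import block_stats, gabriel_blocks, recommended_marker_count
from ldscape.synthetic_data import BlockSpec, SimulationConfig, plant_ld_block

cfg = SimulationConfig(
    n_diploid=200, n_chromosomes=1, markers_per_chromosome=12,
    spacing_bp=50_000, sample_size=200, generations=1, seed=13,
)
ds = plant_ld_block(
    cfg, BlockSpec(chromosome=1, start_marker=4, end_marker=7, hap_freqs=(0.6, 0.4))
)
blocks = gabriel_blocks(ds.genotypes)
for b in blocks:
    print(f"block on chrom {b.chrom}: markers {b.start_idx}..{b.end_idx} "
          f"({b.n_markers} markers, span {b.span_bp / 1e6:.2f} Mb, "
          f"mean spacing {b.mean_spacing_bp / 1e6:.3f} Mb)")

stats = block_stats(blocks)
print(f"size histogram: {{n_markers: count}} = "
      f"{ {int(k): int(v) for k, v in stats.size_histogram.items()} }")
rec = recommended_marker_count(2615.52, stats.mean_spacing_mb)
print(f"markers needed to tile a 2,615.52 Mb genome at the within-block "
      f"spacing: {rec:,d}")
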