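"""In-silico DpnII digestion of a small genome and viewpoint resolution.

Builds a restriction-fragment map for a simulated two-condition experiment's
genome and resolves the assay viewpoint (a promoter position) to its
containing fragment — the anchor every 4C read is assigned relative to.
"""

import fourcat as fc

cfg = fc.default_config(seed=0)
genome, fmap = fc.make_genome(cfg)

print("chromosome sizes:", fmap.chrom_sizes)
for chrom in fmap.chrom_sizes:
    frags = fmap.fragments(chrom)
    mean_len = fmap.chrom_sizes[chrom] / len(frags)
    print(f"  {chrom}: {len(frags):>6} DpnII fragments, mean length {mean_len:.0f} bp")

vp = fc.resolve_viewpoint(fmap, *cfg.viewpoint, name="promoter")
start, end = fmap.fragment_bounds(vp.chrom, vp.fragment_index)
print(
    f"viewpoint {vp.chrom}:{vp.position:,} falls in fragment #{vp.fragment_index} "
    f"[{start:,}, {end:,})"
)
# A random ACGT genome carries GATC roughly every 4^4 = 256 bp, so fragment
# counts ~ chromosome length / 256; the viewpoint fragment is the unit whose
# genome-wide contacts the 4C assay reports.
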