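"""Detect a bridging theme planted between two diverged lineages.

Builds the synthetic two-lineage benchmark (half the families in each
lineage carry the conserved Gly-rich-loop + Asp element), scans it with
the theme profile, validates cross-lineage pairs, and prints the funnel.
"""

from themebridge import RunConfig, run_bridge_pipeline

config = RunConfig(seed=42)
res = run_bridge_pipeline(config)

retained = res.bridge_report[res.bridge_report.retained]
print(f"filtered hits (E<1e-3, cov>=85%, len>=20): {len(res.hits)}")
print(f"bridging themes (hits in both lineages):   {len(res.bridging_themes)}")
print(f"cross-lineage pairs retained at p<0.05:    {len(retained)}")
print("\ntwo representatives (smallest p, most dissimilar flanks):")
for c in res.representatives:
    print(f"  {c.domain_A} ~ {c.domain_B}  mode={c.match_mode} "
          f"p={c.match_pvalue:.2e} flank_score={c.flank_similarity:.0f}")

# The hit count says how many domains carry a detectable copy of the
# theme; a bridging theme means both lineages are among them; a retained
# pair means the two matching segments align far better than segments of
# the same composition ever do by chance, while the flank score stays at
# the random-background level.
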