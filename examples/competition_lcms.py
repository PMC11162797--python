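"""LC-MS competition analysis end to end.

Generates six replicate deconvoluted compound lists for an equimolar
*rC:*araC:*tC competition (truth = the measured +1 composition), matches
records to enumerated candidate products at 10 ppm with sodium-adduct
ladders, and reports normalized incorporation percentages per terminal
sugar under the equal-ionization assumption.
"""

from primex import composition_pipeline, site_reactivity
from primex.synth import DEFAULT_PRIMER_RNA6, PRESETS, competition_monomers

records = PRESETS["competition_1_1_1"].generate(seed=7)
print(f"{len(records)} compound records across 6 replicates")

res = composition_pipeline(
    records, DEFAULT_PRIMER_RNA6, competition_monomers(), depth=1
)
print("\n+1 incorporation (mean ± SD, % of summed +1 abundance):")
for sugar, mean in res.ranked():
    print(f"  {sugar:8s} {mean:5.1f} ± {res.sd_percent[sugar]:.1f}")

r_free = site_reactivity(1.0, 1.6, n_internal=5, n_terminal=2)
r_bound = site_reactivity(0.21, 0.79, n_internal=5, n_terminal=2)
print(f"\nper-site internal 2'-OH reactivity, free primer:  {100*r_free:.0f}%")
print(f"per-site reactivity with complement annealed:     {100*r_bound:.1f}%")
print("\nArabino ranks highest in the equimolar +1 pool and threo lowest;")
print("internal 2'-OH branching is a quarter as reactive per site as the")
print("chain terminus, and drops to ~10% when a complement blocks it.")
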