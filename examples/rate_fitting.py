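"""Pseudo-first-order rate estimation from gel time courses.

Generates a synthetic biphasic time course (a reaction started from
preformed bridged dinucleotide: fast early extension that slows as the
N*N pool hydrolyses), fits windowed kobs values, and compares per-sugar
extension rates as fold ratios.
"""

from primex import fit_kobs, fold_ratio, nearest_fold, windowed_rates
from primex.synth import PRESETS

tcs = PRESETS["bridged_rCrC"].generate(seed=7)
early, late = windowed_rates(tcs, [(0, 8), (8, 52)])
print(f"kobs 0-8 h : {early.k_obs:.3e} ± {early.stderr:.1e} h^-1 "
      f"(n = {early.n_replicates})")
print(f"kobs 8-52 h: {late.k_obs:.3e} ± {late.stderr:.1e} h^-1")

rg = fit_kobs(PRESETS["mono_rG"].generate(seed=7))
tg = fit_kobs(PRESETS["mono_tG"].generate(seed=7))
print(f"\n*rG extension: {rg.k_obs:.2e} h^-1, *tG: {tg.k_obs:.2e} h^-1")
print(f"fold penalty for threo-G: {fold_ratio(rg, tg):.1f}x "
      f"(nearest {nearest_fold(rg, tg)}-fold)")
print("\nThe early/late contrast shows the bridged-dinucleotide transient;")
print("the ~6-fold threo penalty reflects its slower bridged-species")
print("formation (3'-3' coupling is sterically hindered).")
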