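"""Chain-growth competition with arabino termination.

Fits per-sugar incorporation propensities from the equimolar +1
composition, predicts the ribo-enriched (10:1:1) pool composition from
them, and enumerates +2 product sequences under the rule that an arabino
terminus blocks further extension.
"""

from primex import (
    PoolComposition,
    enumerate_products,
    fit_weights,
    predict_step_fractions,
)
from primex.chain import conditional_full_depth

equal = PoolComposition.from_ratio([1, 1, 1])
ten = PoolComposition.from_ratio([10, 1, 1])

pm = fit_weights({"ribo": 0.309, "arabino": 0.447, "threo": 0.244}, equal)
print("fitted propensities:",
      {s: round(w, 3) for s, w in pm.weights.items()})

pred = predict_step_fractions(pm, ten)
print(f"predicted 10:1:1 ribo fraction: {100*pred['ribo']:.1f}% "
      "(measured: 85.8%)")

dist = conditional_full_depth(enumerate_products(pm, ten, depth=2), 2)
print("\n+2 sequences (conditioned on reaching +2):")
for seq, p in sorted(dist.items(), key=lambda kv: -kv[1]):
    print(f"  {'-'.join(seq):16s} {100*p:5.1f}%")
print("\nNo sequence continues past an arabino residue — it is a chain")
print("terminator — so every +2 product starts with a ribo or threo step,")
print("and ribo-ribo dominates, mirroring the measured +2 profile.")
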