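"""Dynamics of the 2AI activation network.

Integrates the mass-action network from 20 mM activated monomer (*N) and
reports the bridged-dinucleotide (N*N) transient: its rise to a few-mM
plateau, suppression by excess free 2AI, and the hydrolysis half-lives
implied by the rate constants.
"""

import numpy as np

from primex import RateConstants, SpeciesState, half_life, simulate

rc = RateConstants()  # defaults: measured constants + calibrated k_rev
times = np.linspace(0, 52, 105)

free = simulate(rc, SpeciesState(activated_mono=20.0, primer=1e-3), times)
supp = simulate(rc, SpeciesState(activated_mono=20.0, two_ai=100.0), times)

peak = free["bridged"].max()
t_peak = free.loc[free["bridged"].idxmax(), "time"]
print(f"bridged N*N peak from 20 mM *N: {peak:.2f} mM at t = {t_peak:.1f} h")
print(f"bridged N*N at 8 h:            {np.interp(8, free.time, free.bridged):.2f} mM")
print(f"with 100 mM 2AI added, max:    {supp['bridged'].max():.3f} mM (suppressed)")
print(f"N*N hydrolysis half-life:      {half_life(rc.k_hyd_bridged):.2f} h")
print(f"*N hydrolysis half-life:       {half_life(rc.k_hyd_mono):.0f} h")
print("\nThe bridged species carries nearly all primer-extension flux; its")
print("few-mM transient explains why reactions seeded with *N alone start")
print("slowly, speed up as N*N forms, then decay as hydrolysis wins.")
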