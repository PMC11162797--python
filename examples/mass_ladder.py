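"""Monoisotopic masses and negative-mode m/z ladders for chimeric oligomers.

Builds an RNA 6-mer primer and its +1 extension products ending in ribo-,
arabino- and threo-cytidine (the ribo monomer carries a uniform 13C/15N
label, as used to break the ribo/arabino isobar), then prints each
product's neutral mass and [M-2H]2- m/z with sodium adducts.
"""

from primex import NucleotideSpec, adducted_mz, homopolymer, oligomer_mass
from primex.chemistry import SODIUM_ADDUCT_MASS

primer = homopolymer("C", 6)  # 5'-OH rC6, 3'-diol
monomers = {
    "rC (13C/15N)": NucleotideSpec("C", "ribo", "13C15N_uniform"),
    "araC": NucleotideSpec("C", "arabino"),
    "tC": NucleotideSpec("C", "threo"),
}

print(f"primer rC6 neutral mass: {oligomer_mass(primer):.4f} Da")
for name, m in monomers.items():
    prod = primer.extended(m)
    mass = oligomer_mass(prod)
    print(f"+1 ending in {name:13s} M = {mass:9.4f} Da", end="  ")
    for n_na in range(3):
        print(f"[M{'+%dNa' % n_na if n_na else ''}-2H]2- = "
              f"{adducted_mz(mass + 0, 2, n_na):8.4f}", end="  ")
    print()
print("\nThe threo product sits 14.0157 Da (one CH2) below the unlabeled")
print("ribo mass; the 13C/15N label lifts ribo ~12 Da above arabino, so all")
print("three +1 products are mass-resolved despite ribo/arabino isobarity.")
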