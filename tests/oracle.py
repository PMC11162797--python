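"""Independent element-summation oracle for oligonucleotide masses.

Deliberately separate from the package: its own atomic-mass table, its own
formula-string parser, and its own oligomer arithmetic, so that agreement
with the package's mass engine is a genuine cross-check.
"""

import re

# AME2020 monoisotopic masses, transcribed independently of the package.
MASSES = {
    "H": 1.007825032,
    "C": 12.0,
    "(13C)": 13.003354835,
    "N": 14.003074004,
    "(15N)": 15.000108899,
    "O": 15.994914620,
    "P": 30.973761998,
    "Na": 22.989769282,
}

_TOKEN = re.compile(r"(\(1[35][CN]\)|[A-Z][a-z]?)(\d*)")

NUCLEOSIDE = {
    ("A", "ribo"): "C10H13N5O4",
    ("G", "ribo"): "C10H13N5O5",
    ("C", "ribo"): "C9H13N3O5",
    ("U", "ribo"): "C9H12N2O6",
}


def parse(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse {formula!r} at {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"trailing junk in {formula!r}")
    return counts


def mass_of(formula: str | dict) -> float:
    counts = parse(formula) if isinstance(formula, str) else formula
    return sum(MASSES[el] * n for el, n in counts.items())


def residue_counts(base: str, sugar: str, labeled: bool = False) -> dict[str, int]:
    counts = dict(parse(NUCLEOSIDE[(base, "ribo")]))
    if sugar == "threo":
        counts["C"] -= 1
        counts["H"] -= 2
    elif sugar == "deoxyribo":
        counts["O"] -= 1
    elif sugar == "dideoxy":
        counts["O"] -= 2
    elif sugar not in ("ribo", "arabino"):
        raise ValueError(sugar)
    if labeled:
        counts["(13C)"] = counts.pop("C")
        counts["(15N)"] = counts.pop("N")
    return counts


def oligomer_mass(
    residues: list[tuple[str, str, bool]],
    five_prime: str = "hydroxyl",
) -> float:
    """residues: list of (base, sugar, labeled). Sums nucleoside masses,
    adds one (H3PO4 - 2 H2O) per linkage, then the 5' end adjustment."""
    total = sum(mass_of(residue_counts(*r)) for r in residues)
    n_link = len(residues) - 1
    total += n_link * (mass_of("H3PO4") - 2 * mass_of("H2O"))
    if five_prime == "hexynyl":
        total += mass_of("C6H8O")
    elif five_prime == "phosphate":
        total += mass_of("HPO3")
    return total
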