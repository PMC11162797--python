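"""Elemental formulas and monoisotopic masses for chimeric oligonucleotides.

Supports ribo (RNA), arabino (ANA), threo (TNA), deoxyribo and dideoxy
residues, uniform stable-isotope labelling (13C/15N), 5' end groups
(hydroxyl, hexynyl, 5'-phosphate) and negative-mode m/z arithmetic with
sodium-adduct ladders.

Chemistry conventions
---------------------
* Arabino-nucleosides are the 2'-epimers of ribonucleosides and are exactly
  isobaric with them; the isotope label is what makes ribo and arabino
  products distinguishable by mass in competition experiments.
* Threo-nucleosides lack the 5'-methylene carbon, so a threo residue is a
  ribo residue minus CH2 (monoisotopic shift -14.01565 Da).  The 3'->2'
  linkage regiochemistry of TNA does not change elemental composition and
  is therefore not mass-bearing.
* A phosphodiester linkage contributes H3PO4 minus two waters
  (net HPO2, +61.95575 Da) per linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "Base",
    "Sugar",
    "Label",
    "FivePrimeEnd",
    "ThreePrimeEnd",
    "NucleotideSpec",
    "OligomerSpec",
    "ElementalFormula",
    "residue_formula",
    "oligomer_formula",
    "monoisotopic_mass",
    "oligomer_mass",
    "adducted_mz",
    "sodium_ladder",
    "oligomer_from_dict",
    "homopolymer",
    "ATOMIC_MASS",
    "PROTON_MASS",
    "SODIUM_ADDUCT_MASS",
    "CH2_MASS",
    "UnsupportedSpeciesError",
]

# Monoisotopic atomic masses (Da, AME2020), pinned for bit-reproducible
# matching.
ATOMIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "13C": 13.0033548350,
    "N": 14.0030740044,
    "15N": 15.0001088989,
    "O": 15.9949146196,
    "P": 30.9737619984,
    "Na": 22.9897692820,
}

PROTON_MASS = 1.007276466
#: mass shift of one H -> Na exchange (Na minus H)
SODIUM_ADDUCT_MASS = ATOMIC_MASS["Na"] - ATOMIC_MASS["H"]
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]


class UnsupportedSpeciesError(ValueError):
    """Raised for base/sugar combinations the engine does not model."""


class Base(str, Enum):
    A = "A"
    C = "C"
    G = "G"
    U = "U"


class Sugar(str, Enum):
    ribo = "ribo"
    arabino = "arabino"
    threo = "threo"
    deoxyribo = "deoxyribo"
    dideoxy = "dideoxy"


class Label(str, Enum):
    none = "none"
    c13n15_uniform = "13C15N_uniform"


class FivePrimeEnd(str, Enum):
    hydroxyl = "hydroxyl"
    hexynyl = "hexynyl"
    phosphate = "phosphate"


class ThreePrimeEnd(str, Enum):
    diol = "diol"
    dideoxy = "dideoxy"


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts over {C, 13C, H, N, 15N, O, P, Na}.

    Arithmetic (+, -, int *) is supported; intermediate results may carry
    negative counts (e.g. the per-linkage water subtraction) but
    :meth:`validated` must succeed on any formula handed to mass routines.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {el: int(n) for el, n in self.counts.items() if n != 0}
        )

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return self + (other * -1)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def validated(self) -> "ElementalFormula":
        bad = {el: n for el, n in self.counts.items() if n < 0}
        if bad:
            raise ValueError(f"negative element counts: {bad}")
        return self

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Hill-order formula string (labels shown as [13C]/[15N])."""
        order = ["C", "13C", "H", "N", "15N", "O", "P", "Na"]
        parts = []
        for el in order:
            n = self.counts.get(el, 0)
            if n:
                sym = f"[{el}]" if el in ("13C", "15N") else el
                parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts) or "(empty)"


def _f(**counts: int) -> ElementalFormula:
    return ElementalFormula(counts)


# Free ribonucleoside formulas (base + ribose, glycosidic water removed).
_RIBONUCLEOSIDE: Mapping[Base, ElementalFormula] = {
    Base.A: _f(C=10, H=13, N=5, O=4),
    Base.G: _f(C=10, H=13, N=5, O=5),
    Base.C: _f(C=9, H=13, N=3, O=5),
    Base.U: _f(C=9, H=12, N=2, O=6),
}

_WATER = _f(H=2, O=1)
_PHOSPHORIC_ACID = _f(H=3, P=1, O=4)  # H3PO4
_HPO3 = _f(H=1, P=1, O=3)
_HEXYNYL = _f(C=6, H=8, O=1)  # net change of 5'-H -> hex-5-ynyl ether


@dataclass(frozen=True)
class NucleotideSpec:
    """Chemical identity of one residue: base, sugar family, isotope label."""

    base: Base
    sugar: Sugar = Sugar.ribo
    label: Label = Label.none

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", Base(self.base))
        object.__setattr__(self, "sugar", Sugar(self.sugar))
        object.__setattr__(self, "label", Label(self.label))


@dataclass(frozen=True)
class OligomerSpec:
    """An oligonucleotide chain, 5'->3', with explicit end groups."""

    residues: tuple[NucleotideSpec, ...]
    five_prime_end: FivePrimeEnd = FivePrimeEnd.hydroxyl
    three_prime_end: ThreePrimeEnd = ThreePrimeEnd.diol

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "five_prime_end", FivePrimeEnd(self.five_prime_end))
        object.__setattr__(self, "three_prime_end", ThreePrimeEnd(self.three_prime_end))
        if not self.residues:
            raise ValueError("oligomer must contain at least one residue")

    @property
    def n_internucleotide_linkages(self) -> int:
        return len(self.residues) - 1

    def extended(self, *added: NucleotideSpec) -> "OligomerSpec":
        """A copy with residues appended at the 3' terminus."""
        return OligomerSpec(
            self.residues + tuple(added), self.five_prime_end, self.three_prime_end
        )

    def n_internal_2oh(self) -> int:
        """Count of internal residues bearing a free 2'-OH (ribo only;
        arabino 2'-OH faces the other way but still counts chemically —
        here only ribo/arabino internal residues are nucleophilic)."""
        return sum(
            1
            for r in self.residues[:-1]
            if r.sugar in (Sugar.ribo, Sugar.arabino)
        )


def residue_formula(spec: NucleotideSpec) -> ElementalFormula:
    """Free-nucleoside elemental formula for one residue spec.

    Uniform labelling replaces every C with 13C and every N with 15N.
    """
    try:
        f = _RIBONUCLEOSIDE[Base(spec.base)]
    except (KeyError, ValueError) as exc:
        raise UnsupportedSpeciesError(f"unknown base {spec.base!r}") from exc
    sugar = Sugar(spec.sugar)
    if sugar == Sugar.ribo or sugar == Sugar.arabino:
        pass  # epimers: identical composition
    elif sugar == Sugar.threo:
        f = f - _f(C=1, H=2)
    elif sugar == Sugar.deoxyribo:
        f = f - _f(O=1)
    elif sugar == Sugar.dideoxy:
        f = f - _f(O=2)
    else:  # pragma: no cover - enum is closed
        raise UnsupportedSpeciesError(f"unknown sugar {spec.sugar!r}")
    f = f.validated()
    if Label(spec.label) == Label.c13n15_uniform:
        c = f.counts.get("C", 0)
        n = f.counts.get("N", 0)
        f = ElementalFormula(
            {
                **{el: k for el, k in f.counts.items() if el not in ("C", "N")},
                "13C": f.counts.get("13C", 0) + c,
                "15N": f.counts.get("15N", 0) + n,
            }
        )
    return f


def oligomer_formula(oligo: OligomerSpec) -> ElementalFormula:
    """Elemental formula of a full oligomer.

    Sum of free-nucleoside formulas, plus one phosphodiester linkage term
    (H3PO4 - 2 H2O) per linkage, plus 5' end-group adjustment.  Dideoxy 3'
    termini are carried by the terminal residue's sugar.
    """
    total = ElementalFormula()
    for r in oligo.residues:
        total = total + residue_formula(r)
    n_link = oligo.n_internucleotide_linkages
    total = total + n_link * _PHOSPHORIC_ACID - (2 * n_link) * _WATER
    if oligo.five_prime_end == FivePrimeEnd.hexynyl:
        total = total + _HEXYNYL
    elif oligo.five_prime_end == FivePrimeEnd.phosphate:
        total = total + _HPO3
    return total.validated()


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of count x atomic monoisotopic mass over the formula."""
    mass = 0.0
    for el, n in f.counts.items():
        if n < 0:
            raise ValueError(f"negative count for {el}")
        try:
            mass += n * ATOMIC_MASS[el]
        except KeyError as exc:
            raise KeyError(f"unknown element symbol {el!r}") from exc
    return mass


def oligomer_mass(oligo: OligomerSpec) -> float:
    return monoisotopic_mass(oligomer_formula(oligo))


def adducted_mz(neutral_mass: float, charge: int, n_sodium: int = 0) -> float:
    """Negative-mode m/z of an [M + nNa - nH - zH]^z- species.

    ``charge`` is the charge-state magnitude z (>= 1).  Each sodium adduct
    exchanges one proton for Na (+21.98194 Da); the caller is responsible
    for not exceeding the number of exchangeable protons (not checked).
    """
    if charge < 1:
        raise ValueError("charge-state magnitude must be >= 1")
    if n_sodium < 0:
        raise ValueError("n_sodium must be >= 0")
    return (neutral_mass + n_sodium * SODIUM_ADDUCT_MASS - charge * PROTON_MASS) / charge


def sodium_ladder(neutral_mass: float, max_sodium: int) -> list[float]:
    """Neutral masses of the sodium-adduct series M, M+Na-H, ..."""
    return [neutral_mass + k * SODIUM_ADDUCT_MASS for k in range(max_sodium + 1)]


def oligomer_from_dict(d: Mapping) -> OligomerSpec:
    """Build an :class:`OligomerSpec` from the JSON dialect
    ``{"residues": [{"base": "C", "sugar": "ribo", "label": "none"}, ...],
    "five_prime_end": "hydroxyl", "three_prime_end": "diol"}``."""
    residues = tuple(
        NucleotideSpec(
            base=r["base"], sugar=r.get("sugar", "ribo"), label=r.get("label", "none")
        )
        for r in d["residues"]
    )
    return OligomerSpec(
        residues,
        five_prime_end=d.get("five_prime_end", "hydroxyl"),
        three_prime_end=d.get("three_prime_end", "diol"),
    )


def homopolymer(
    base: Base | str,
    n: int,
    sugar: Sugar | str = Sugar.ribo,
    label: Label | str = Label.none,
    five_prime_end: FivePrimeEnd | str = FivePrimeEnd.hydroxyl,
    three_prime_end: ThreePrimeEnd | str = ThreePrimeEnd.diol,
) -> OligomerSpec:
    """Convenience constructor, e.g. ``homopolymer("C", 6)`` for an rC 6-mer."""
    spec = NucleotideSpec(Base(base), Sugar(sugar), Label(label))
    return OligomerSpec((spec,) * n, five_prime_end, three_prime_end)
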