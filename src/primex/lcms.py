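"""LC-MS compound matching and incorporation quantification.

Inputs are vendor-style deconvoluted compound lists (neutral monoisotopic
mass, retention time, abundance, replicate).  Candidates are enumerated
extension products of a primer; records are assigned to the candidate whose
sodium-adduct mass ladder matches best in ppm.  Normalized incorporation
percentages per terminal sugar follow under the equal-ionization assumption
(same-length oligomers differing only in terminal sugar ionize equally),
with abundances of adduct records and co-eluting doublet peaks summed into
the parent compound identity before normalization.

Retention time is never used for identity: linkage regioisomers and
terminal/internal-branch isomers co-elute or are isobaric, so identity
rests on mass alone (and on primer design upstream).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chemistry import (
    SODIUM_ADDUCT_MASS,
    NucleotideSpec,
    OligomerSpec,
    oligomer_mass,
    sodium_ladder,
)

__all__ = [
    "CompoundRecord",
    "CandidateProduct",
    "Match",
    "MatchTable",
    "CompositionResult",
    "enumerate_candidates",
    "match",
    "incorporation_percentages",
    "site_reactivity",
    "composition_pipeline",
]


@dataclass(frozen=True)
class CompoundRecord:
    neutral_mass: float       # Da
    retention_time: float     # min
    abundance: float          # arbitrary units >= 0
    replicate: str

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be > 0")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass(frozen=True)
class CandidateProduct:
    oligomer: OligomerSpec
    depth: int                           # 0 = unextended primer
    added: tuple[NucleotideSpec, ...]    # residues added, 5'->3'
    terminal_sugar: str | None           # sugar of the last added residue
    site_class: str                      # "terminal" | "internal_branch"
    neutral_mass: float                  # Da

    @property
    def key(self) -> tuple:
        """Identity used for abundance aggregation."""
        seq = tuple(r.sugar.value for r in self.added)
        return (self.depth, seq, self.site_class)

    def label(self) -> str:
        if self.depth == 0:
            return "primer"
        seq = "+".join(r.sugar.value[0:3] + r.base.value for r in self.added)
        tag = "" if self.site_class == "terminal" else " (2'-branch)"
        return f"+{seq}{tag}"


@dataclass(frozen=True)
class Match:
    record: CompoundRecord
    candidate: CandidateProduct
    ppm_error: float
    n_sodium: int


@dataclass(frozen=True)
class MatchTable:
    matches: tuple[Match, ...]
    unmatched: tuple[CompoundRecord, ...]
    ambiguous: tuple[CompoundRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": [m.record.replicate for m in self.matches],
                "neutral_mass_da": [m.record.neutral_mass for m in self.matches],
                "abundance": [m.record.abundance for m in self.matches],
                "candidate": [m.candidate.label() for m in self.matches],
                "depth": [m.candidate.depth for m in self.matches],
                "terminal_sugar": [m.candidate.terminal_sugar for m in self.matches],
                "site_class": [m.candidate.site_class for m in self.matches],
                "n_sodium": [m.n_sodium for m in self.matches],
                "ppm_error": [m.ppm_error for m in self.matches],
            }
        )


@dataclass(frozen=True)
class CompositionResult:
    """Normalized incorporation per terminal sugar at one extension depth."""

    depth: int
    mean_percent: Mapping[str, float]
    sd_percent: Mapping[str, float]
    n_replicates: int

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.mean_percent.items(), key=lambda kv: -kv[1])


def enumerate_candidates(
    primer: OligomerSpec,
    monomers: Sequence[NucleotideSpec],
    max_depth: int = 1,
    include_primer: bool = True,
) -> list[CandidateProduct]:
    """All extension products of ``primer`` up to ``max_depth`` additions.

    Terminal candidates cover every monomer sequence of length 1..max_depth.
    Internal-branch candidates (addition at a free internal 2'-OH, one extra
    residue and one extra linkage, chain termini unchanged) are generated
    only when the primer has internal 2'-OH groups — e.g. suppressed for a
    DNA-body primer with a single 3'-terminal ribonucleotide.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    out: list[CandidateProduct] = []
    if include_primer:
        out.append(
            CandidateProduct(
                primer, 0, (), None, "terminal", oligomer_mass(primer)
            )
        )
    for depth in range(1, max_depth + 1):
        for combo in itertools.product(monomers, repeat=depth):
            ext = primer.extended(*combo)
            out.append(
                CandidateProduct(
                    ext,
                    depth,
                    combo,
                    combo[-1].sugar.value,
                    "terminal",
                    oligomer_mass(ext),
                )
            )
    if primer.n_internal_2oh() > 0:
        # branch formation is a single addition; deeper branched species are
        # not enumerated (their abundance is negligible at +2 in practice)
        for m in monomers:
            branched = primer.extended(m)  # same composition as terminal +1
            out.append(
                CandidateProduct(
                    branched,
                    1,
                    (m,),
                    m.sugar.value,
                    "internal_branch",
                    oligomer_mass(branched),
                )
            )
    return out


def match(
    records: Sequence[CompoundRecord],
    candidates: Sequence[CandidateProduct],
    tol_ppm: float = 10.0,
    max_sodium: int = 3,
) -> MatchTable:
    """Assign each record to its best candidate within ``tol_ppm``.

    Each record is tested against every candidate's neutral mass and its
    sodium-adduct ladder (M + k*(Na-H), k <= max_sodium); the smallest
    absolute ppm error wins.  Ties between candidates at genuinely
    different masses are flagged ambiguous and excluded from
    quantification; ties between isobaric candidates are resolved
    deterministically in favour of terminal-site candidates.
    Matching is independent of record order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    ladders = [
        (c, sodium_ladder(c.neutral_mass, max_sodium)) for c in candidates
    ]
    matches: list[Match] = []
    unmatched: list[CompoundRecord] = []
    ambiguous: list[CompoundRecord] = []
    for rec in records:
        best: list[tuple[float, int, CandidateProduct]] = []
        for cand, ladder in ladders:
            for n_na, m in enumerate(ladder):
                ppm = (rec.neutral_mass - m) / m * 1e6
                if abs(ppm) <= tol_ppm:
                    best.append((abs(ppm), n_na, cand))
        if not best:
            unmatched.append(rec)
            continue
        best_abs = min(b[0] for b in best)
        top = [b for b in best if abs(b[0] - best_abs) < 1e-12]
        masses = {round(b[2].neutral_mass, 6) for b in top}
        if len(masses) > 1:
            ambiguous.append(rec)
            continue
        # isobaric tie: prefer terminal site class, then enumeration order
        top.sort(key=lambda b: (b[2].site_class != "terminal",))
        _, n_na, cand = top[0]
        ladder_mass = cand.neutral_mass + n_na * SODIUM_ADDUCT_MASS
        signed = (rec.neutral_mass - ladder_mass) / ladder_mass * 1e6
        matches.append(Match(rec, cand, signed, n_na))
    return MatchTable(tuple(matches), tuple(unmatched), tuple(ambiguous))


def incorporation_percentages(
    mt: MatchTable,
    depth: int = 1,
    response_factors: Mapping[str, float] | None = None,
) -> CompositionResult:
    """Normalized incorporation per terminal sugar at ``depth``.

    Per replicate: percent_i = 100 * A_i / sum_j A_j over terminal sugars,
    where A_i sums every matched record assigned to a candidate with
    terminal sugar i at that depth (adducts and doublet peaks included).
    Mean and SD (ddof=1) are taken across replicates.  ``response_factors``
    optionally divides each sugar's abundance by a relative ionization
    response (default: equal ionization).
    """
    df = mt.to_frame()
    df = df[df["depth"] == depth]
    if df.empty:
        raise ValueError(f"no matched products at depth {depth}")
    if response_factors:
        df = df.assign(
            abundance=df["abundance"]
            / df["terminal_sugar"].map(lambda s: response_factors.get(s, 1.0))
        )
    per_rep = (
        df.groupby(["replicate", "terminal_sugar"], sort=True)["abundance"]
        .sum()
        .unstack(fill_value=0.0)
    )
    totals = per_rep.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} replicate(s) with zero total abundance"
        )
        per_rep = per_rep[~zero]
        totals = totals[~zero]
    if per_rep.empty:
        raise ValueError("all replicates had zero total abundance")
    pct = per_rep.div(totals, axis=0) * 100.0
    mean = pct.mean(axis=0)
    sd = pct.std(axis=0, ddof=1) if len(pct) > 1 else pct.iloc[0] * 0.0
    return CompositionResult(
        depth=depth,
        mean_percent=dict(mean),
        sd_percent=dict(sd),
        n_replicates=len(pct),
    )


def site_reactivity(
    f_internal: float,
    f_terminal: float,
    n_internal: int = 5,
    n_terminal: int = 2,
) -> float:
    """Per-site internal/terminal hydroxyl reactivity ratio.

    r = (f_internal / n_internal) / (f_terminal / n_terminal), where the f
    are total product fractions (any common scale) and the n are reactive
    site counts.  E.g. a 1:1.6 internal:terminal product ratio over 5
    internal and 2 terminal hydroxyls gives r = 0.25: each internal 2'-OH
    is on average ~25% as reactive as a terminal hydroxyl.
    """
    if f_internal < 0 or f_terminal < 0 or (f_internal == 0 and f_terminal == 0):
        raise ValueError("fractions must be >= 0 and not both zero")
    if n_internal < 1 or n_terminal < 1:
        raise ValueError("site counts must be >= 1")
    if f_terminal == 0:
        raise ZeroDivisionError("per-site ratio undefined for f_terminal = 0")
    return (f_internal / n_internal) / (f_terminal / n_terminal)


def composition_pipeline(
    records: Sequence[CompoundRecord],
    primer: OligomerSpec,
    monomers: Sequence[NucleotideSpec],
    depth: int = 1,
    max_depth: int | None = None,
    tol_ppm: float = 10.0,
    max_sodium: int = 3,
) -> CompositionResult:
    """Enumerate candidates, match records, and quantify in one call."""
    cands = enumerate_candidates(
        primer, monomers, max_depth=max_depth if max_depth is not None else depth
    )
    mt = match(records, cands, tol_ppm=tol_ppm, max_sodium=max_sodium)
    return incorporation_percentages(mt, depth=depth)
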