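"""Synthetic measurement generator for the three assay types.

Emulates, with explicit noise models and mandatory seeds:

* gel time courses — P/P0 = clip(exp(-k t) * (1 + eps), 0, 1) with
  multiplicative Gaussian noise (CV default 5%), 2-3 replicates;
* 31P-NMR-like species concentration series — mass-action trajectories
  with multiplicative noise and an optional renormalization to the known
  20 mM total nucleotide concentration;
* LC-MS compound lists — per-replicate product abundances drawn from a
  Dirichlet around the true composition (concentration parameter chosen so
  replicate SDs approximate the measured run-to-run scatter), masses
  perturbed by Gaussian ppm error, and sodium-adduct records split off.

What it does NOT emulate: raw chromatograms/spectra/gel images, retention
behaviour, ionization suppression, cross-batch dry-down variability (an
effective-rate multiplier preset stands in for drying acceleration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    SODIUM_ADDUCT_MASS,
    Base,
    Label,
    NucleotideSpec,
    OligomerSpec,
    Sugar,
    homopolymer,
)
from .lcms import CompoundRecord, enumerate_candidates
from .network import RateConstants, SpeciesState, simulate
from .rates import ExtensionTimeCourse

__all__ = [
    "gen_gel_timecourse",
    "gen_piecewise_gel_timecourse",
    "gen_species_timecourse",
    "gen_compound_list",
    "ScenarioPreset",
    "PRESETS",
    "competition_monomers",
    "DEFAULT_PRIMER_RNA6",
    "DEFAULT_PRIMER_TERMINAL_ONLY",
]

#: Dirichlet concentration giving replicate SDs of ~2.5-3.5 percentage
#: points at mid-range compositions, matching the observed scatter of the
#: six-replicate competition measurements.
DEFAULT_DIRICHLET_CONCENTRATION = 200.0

# 6-mer 5'-OH RNA primer (free internal 2'-OHs; both terminal hydroxyls).
DEFAULT_PRIMER_RNA6 = homopolymer("C", 6)
# 5'-hexynyl DNA primer with a single 3'-terminal ribonucleotide: only the
# terminal diol can react, so no internal-branch products form.
DEFAULT_PRIMER_TERMINAL_ONLY = OligomerSpec(
    tuple(NucleotideSpec(Base.C, Sugar.deoxyribo) for _ in range(5))
    + (NucleotideSpec(Base.C, Sugar.ribo),),
    five_prime_end="hexynyl",
)


def competition_monomers() -> list[NucleotideSpec]:
    """The competition monomer set: isotope-labelled rC (to break the
    ribo/arabino isobar), unlabelled araC and tC."""
    return [
        NucleotideSpec(Base.C, Sugar.ribo, Label.c13n15_uniform),
        NucleotideSpec(Base.C, Sugar.arabino),
        NucleotideSpec(Base.C, Sugar.threo),
    ]


def gen_gel_timecourse(
    k_true: float,
    times: Sequence[float],
    n_reps: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[ExtensionTimeCourse]:
    """Exponential primer-decay gel series with multiplicative noise."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    out = []
    for r in range(n_reps):
        eps = rng.normal(0.0, noise_cv, size=len(t)) if noise_cv else 0.0
        p = np.clip(np.exp(-k_true * t) * (1 + eps), 0.0, 1.0)
        out.append(ExtensionTimeCourse(f"rep{r + 1}", tuple(t), tuple(p)))
    return out


def gen_piecewise_gel_timecourse(
    k_segments: Sequence[tuple[float, float]],
    times: Sequence[float],
    n_reps: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[ExtensionTimeCourse]:
    """Piecewise-exponential decay, e.g. fast 0-8 h then slow 8-52 h.

    ``k_segments`` is [(t_end_1, k_1), (t_end_2, k_2), ...] with increasing
    segment ends covering the grid; the decay is continuous.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    log_p = np.zeros_like(t)
    t_prev = 0.0
    for t_end, k in k_segments:
        seg = np.clip(t, t_prev, t_end) - t_prev
        log_p -= k * seg
        t_prev = t_end
    out = []
    for r in range(n_reps):
        eps = rng.normal(0.0, noise_cv, size=len(t)) if noise_cv else 0.0
        p = np.clip(np.exp(log_p) * (1 + eps), 0.0, 1.0)
        out.append(ExtensionTimeCourse(f"rep{r + 1}", tuple(t), tuple(p)))
    return out


def gen_species_timecourse(
    rc: RateConstants,
    state0: SpeciesState,
    times: Sequence[float],
    noise_cv: float = 0.03,
    seed: int = 0,
    renormalize_total: float | None = None,
) -> pd.DataFrame:
    """NMR-like species series: simulate() plus multiplicative noise.

    With ``renormalize_total`` set (mM), each time point's noisy
    {activated_mono, bridged, nmp} concentrations are rescaled so the
    nucleotide-unit sum *N + 2 N*N + NMP equals that total exactly —
    mirroring conversion of peak integrals to concentrations against a
    known total.
    """
    df = simulate(rc, state0, times)
    rng = np.random.default_rng(seed)
    noisy = df.copy()
    species = [c for c in df.columns if c != "time"]
    if noise_cv:
        for c in species:
            noisy[c] = df[c] * (1 + rng.normal(0.0, noise_cv, size=len(df)))
        noisy[species] = noisy[species].clip(lower=0.0)
    if renormalize_total is not None:
        units = (
            noisy["activated_mono"] + 2 * noisy["bridged"] + noisy["nmp"]
        )
        scale = np.where(units > 0, renormalize_total / units, 1.0)
        for c in ("activated_mono", "bridged", "nmp"):
            noisy[c] = noisy[c] * scale
    return noisy


def gen_compound_list(
    true_fractions: Mapping[int, Mapping[str, float]],
    primer: OligomerSpec,
    monomers: Sequence[NucleotideSpec] | None = None,
    n_reps: int = 6,
    mass_ppm_sd: float = 5.0,
    adduct_probs: Sequence[float] = (0.8, 0.15, 0.05),
    dirichlet_concentration: float = DEFAULT_DIRICHLET_CONCENTRATION,
    abundance_dispersion: float = 0.2,
    base_abundance: float = 1e6,
    doublet_split: Sequence[float] | None = None,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Vendor-style deconvoluted compound list for a competition run.

    ``true_fractions`` maps extension depth -> {sugar or sugar-sequence
    string (e.g. "ribo" or "ribo,arabino"): fraction}; fractions at each
    depth must lie on the simplex.  Per replicate and depth, product
    fractions are Dirichlet(concentration * truth); each product's total
    abundance (lognormal dispersion around ``base_abundance``) is split
    across the sodium-adduct series by ``adduct_probs``; every record's
    mass is the candidate mass times (1 + N(0, ppm_sd * 1e-6)), truncated
    at 4 sd.

    Primers with free internal 2'-OHs give a chromatographic double peak
    per +1 product (terminal extension vs isobaric internal branch); each
    such product is emitted as two peaks at distinct retention times with
    the measured ~1.6:1 terminal:internal abundance split.  Pass
    ``doublet_split`` to override, e.g. ``(1.0,)`` for a single peak;
    terminal-only primers (no internal 2'-OH) always give single peaks.
    """
    if monomers is None:
        monomers = competition_monomers()
    adduct_probs = np.asarray(adduct_probs, dtype=float)
    adduct_probs = adduct_probs / adduct_probs.sum()
    rng = np.random.default_rng(seed)
    max_depth = max(true_fractions)
    cands = enumerate_candidates(primer, list(monomers), max_depth=max_depth)
    terminal = {
        (c.depth, tuple(r.sugar.value for r in c.added)): c
        for c in cands
        if c.site_class == "terminal" and c.depth >= 1
    }
    if doublet_split is None:
        # measured terminal:internal product ratio ~1.6:1 for primers with
        # free internal 2'-OHs; terminal-only primers give single peaks
        if primer.n_internal_2oh() > 0:
            doublet_split = (1.6 / 2.6, 1.0 / 2.6)
        else:
            doublet_split = (1.0,)
    records: list[CompoundRecord] = []
    for rep in range(1, n_reps + 1):
        rep_id = f"rep{rep}"
        for depth, fracs in true_fractions.items():
            keys = list(fracs)
            p = np.array([fracs[k] for k in keys], dtype=float)
            if abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValueError(f"fractions at depth {depth} are off the simplex")
            alive = p > 0
            drawn = np.zeros_like(p)
            drawn[alive] = rng.dirichlet(dirichlet_concentration * p[alive])
            total = base_abundance * rng.lognormal(0.0, abundance_dispersion)
            peak_split = doublet_split if depth == 1 else (1.0,)
            for key, frac in zip(keys, drawn):
                if frac == 0:
                    continue
                seq = tuple(s.strip() for s in key.split(","))
                cand = terminal[(depth, seq)]
                # deterministic per-product retention slot + jitter (identity
                # never depends on it); hash() is salted, so use ordinals
                slot = sum(ord(ch) for s in seq for ch in s) % 7
                for i_peak, peak_frac in enumerate(peak_split):
                    rt = (
                        5.0 + 0.8 * depth + 0.1 * slot + 0.35 * i_peak
                        + rng.normal(0, 0.05)
                    )
                    for n_na, ap in enumerate(adduct_probs):
                        if ap == 0:
                            continue
                        m = cand.neutral_mass + n_na * SODIUM_ADDUCT_MASS
                        # mass error truncated at 4 sd: deconvoluted compound
                        # masses never stray arbitrarily far from the species
                        delta = rng.normal(0.0, 1.0)
                        while abs(delta) > 4.0:
                            delta = rng.normal(0.0, 1.0)
                        obs = m * (1 + delta * mass_ppm_sd * 1e-6)
                        records.append(
                            CompoundRecord(
                                neutral_mass=float(obs),
                                retention_time=float(rt),
                                abundance=float(total * frac * peak_frac * ap),
                                replicate=rep_id,
                            )
                        )
    return records


@dataclass(frozen=True)
class ScenarioPreset:
    """A named study condition: truths, replicate counts, noise, primer."""

    name: str
    kind: str  # "gel" | "nmr" | "lcms"
    params: Mapping = field(default_factory=dict)

    def generate(self, seed: int):
        p = dict(self.params)
        if self.kind == "gel":
            segs = p.pop("k_segments", None)
            if segs is not None:
                return gen_piecewise_gel_timecourse(segs, seed=seed, **p)
            return gen_gel_timecourse(seed=seed, **p)
        if self.kind == "nmr":
            return gen_species_timecourse(seed=seed, **p)
        if self.kind == "lcms":
            return gen_compound_list(seed=seed, **p)
        raise ValueError(f"unknown preset kind {self.kind!r}")


_GEL_TIMES_INITIAL = tuple(np.linspace(0.0, 8.0, 9))
_GEL_TIMES_FULL = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 52.0)
_GEL_TIMES_SLOW = tuple(np.linspace(0.0, 500.0, 11))
_NMR_TIMES = tuple(np.linspace(0.0, 52.0, 27))

PRESETS: dict[str, ScenarioPreset] = {
    # gel kinetics: preformed bridged dinucleotide start — fast then slow
    "bridged_rCrC": ScenarioPreset(
        "bridged_rCrC",
        "gel",
        {
            "k_segments": ((8.0, 2.5e-2), (52.0, 1.2e-2)),
            "times": _GEL_TIMES_FULL,
            "n_reps": 3,
            "noise_cv": 0.05,
        },
    ),
    # activated monomer start, initial window
    "mono_rC": ScenarioPreset(
        "mono_rC",
        "gel",
        {"k_true": 5e-3, "times": _GEL_TIMES_FULL, "n_reps": 3, "noise_cv": 0.05},
    ),
    # monomer + excess 2AI: below the gel detectability floor
    "mono_rC_2AI": ScenarioPreset(
        "mono_rC_2AI",
        "gel",
        {"k_true": 1e-4, "times": _GEL_TIMES_FULL, "n_reps": 3, "noise_cv": 0.05},
    ),
    # per-sugar guanosine series; ~1e-3 h^-1 rates need a long sampling
    # window to resolve at 5% band noise
    "mono_rG": ScenarioPreset(
        "mono_rG",
        "gel",
        {"k_true": 2.2e-3, "times": _GEL_TIMES_SLOW, "n_reps": 2, "noise_cv": 0.05},
    ),
    "mono_araG": ScenarioPreset(
        "mono_araG",
        "gel",
        {"k_true": 1.8e-3, "times": _GEL_TIMES_SLOW, "n_reps": 2, "noise_cv": 0.05},
    ),
    "mono_tG": ScenarioPreset(
        "mono_tG",
        "gel",
        {"k_true": 3.6e-4, "times": _GEL_TIMES_SLOW, "n_reps": 2, "noise_cv": 0.05},
    ),
    # NMR: pure bridged hydrolysis from 20 mM
    "hydrolysis_NN": ScenarioPreset(
        "hydrolysis_NN",
        "nmr",
        {
            "rc": RateConstants(
                k_form=0.0, k_rev=0.0, k_hyd_bridged=0.105, k_hyd_mono=1.96e-3,
                k_ext_bridged=0.0, k_ext_mono=0.0,
            ),
            "state0": SpeciesState(bridged=20.0),
            "times": _NMR_TIMES,
            "noise_cv": 0.03,
        },
    ),
    # NMR: equilibration from 20 mM activated monomer (full default network)
    "equilibration_starN": ScenarioPreset(
        "equilibration_starN",
        "nmr",
        {
            "rc": RateConstants(),
            "state0": SpeciesState(activated_mono=20.0, primer=1e-3),
            "times": _NMR_TIMES,
            "noise_cv": 0.03,
        },
    ),
    # LC-MS competition scenarios (truths are the measured compositions)
    "competition_1_1_1": ScenarioPreset(
        "competition_1_1_1",
        "lcms",
        {
            "true_fractions": {1: {"ribo": 0.309, "arabino": 0.447, "threo": 0.244}},
            "primer": DEFAULT_PRIMER_RNA6,
            "n_reps": 6,
        },
    ),
    "competition_10_1_1": ScenarioPreset(
        "competition_10_1_1",
        "lcms",
        {
            "true_fractions": {
                1: {"ribo": 0.858, "arabino": 0.084, "threo": 0.058},
                # measured +2 composition (83.9/11.5/4.5) renormalized to
                # the simplex
                2: {
                    "ribo,ribo": 0.839 / 0.999,
                    "ribo,arabino": 0.115 / 0.999,
                    "ribo,threo": 0.045 / 0.999,
                },
            },
            "primer": DEFAULT_PRIMER_RNA6,
            "n_reps": 6,
        },
    ),
    "competition_1_1_1_terminalonly": ScenarioPreset(
        "competition_1_1_1_terminalonly",
        "lcms",
        {
            # measured 39.0/45.0/16.1 renormalized to the simplex
            "true_fractions": {
                1: {
                    "ribo": 0.390 / 1.001,
                    "arabino": 0.450 / 1.001,
                    "threo": 0.161 / 1.001,
                }
            },
            "primer": DEFAULT_PRIMER_TERMINAL_ONLY,
            "n_reps": 6,
        },
    ),
    "competition_10_1_1_terminalonly": ScenarioPreset(
        "competition_10_1_1_terminalonly",
        "lcms",
        {
            # measured 89.2/8.3/2.6 renormalized to the simplex
            "true_fractions": {
                1: {
                    "ribo": 0.892 / 1.001,
                    "arabino": 0.083 / 1.001,
                    "threo": 0.026 / 1.001,
                }
            },
            "primer": DEFAULT_PRIMER_TERMINAL_ONLY,
            "n_reps": 6,
        },
    ),
    # pH series (guanosine monomer + 2AI); these ~1e-4 h^-1 rates need a
    # weeks-long sampling window to be resolvable at 5% band noise
    "pH7": ScenarioPreset(
        "pH7", "gel",
        {"k_true": 1.9e-4, "times": _GEL_TIMES_SLOW, "n_reps": 3, "noise_cv": 0.05},
    ),
    "pH8": ScenarioPreset(
        "pH8", "gel",
        {"k_true": 5.3e-4, "times": _GEL_TIMES_SLOW, "n_reps": 3, "noise_cv": 0.05},
    ),
    "pH9": ScenarioPreset(
        "pH9", "gel",
        {"k_true": 8.1e-4, "times": _GEL_TIMES_SLOW, "n_reps": 3, "noise_cv": 0.05},
    ),
}
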