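"""Copolymerization competition model with chain termination.

A memoryless per-step model of non-templated chain growth from a mixed
monomer pool: at each step the probability that sugar i is added is

    f_i = w_i * x_i / sum_j w_j * x_j

where x is the pool mole fraction and w a relative incorporation
propensity.  Whether the chain continues past a newly added residue is
governed by a terminal-sugar-dependent extendability e(s) in [0, 1]:
e(arabino) = 0 by default (an arabino terminus is a chain terminator),
e(ribo) = 1, and e(threo) defaults to 0.17, mapping the ~6-fold rate
penalty of threo- vs ribo-guanosine extension onto a relative
continuation probability (a documented modelling assumption).

Chains that stop before the maximum depth are reported as their own
outcome class (gels and LC-MS observe them), not renormalized away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PropensityModel",
    "PoolComposition",
    "predict_step_fractions",
    "fit_weights",
    "enumerate_products",
    "sample_chains",
    "DEFAULT_EXTENDABILITY",
]

DEFAULT_EXTENDABILITY: Mapping[str, float] = {
    "ribo": 1.0,
    "arabino": 0.0,
    "threo": 0.17,
}


@dataclass(frozen=True)
class PropensityModel:
    """Relative incorporation weights and terminal extendabilities."""

    weights: Mapping[str, float]
    extendability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTENDABILITY)
    )

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        e = dict(self.extendability)
        if any(not (0 <= v <= 1) for v in e.values()):
            raise ValueError("extendability must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "extendability", e)

    def e(self, sugar: str) -> float:
        return self.extendability.get(sugar, 1.0)


@dataclass(frozen=True)
class PoolComposition:
    """Input mole fractions per sugar, e.g. from a 10:1:1 mixing ratio."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        x = {k: float(v) for k, v in self.fractions.items()}
        if any(v < 0 for v in x.values()):
            raise ValueError("mole fractions must be >= 0")
        s = sum(x.values())
        if s <= 0:
            raise ValueError("pool must have positive total")
        if abs(s - 1) > 1e-9:
            x = {k: v / s for k, v in x.items()}
        object.__setattr__(self, "fractions", x)

    @classmethod
    def from_ratio(cls, ratio: Mapping[str, float] | Sequence[float], sugars=("ribo", "arabino", "threo")):
        """e.g. ``from_ratio([10, 1, 1])`` -> x = (10/12, 1/12, 1/12)."""
        if not isinstance(ratio, Mapping):
            ratio = dict(zip(sugars, ratio))
        return cls(ratio)


def predict_step_fractions(
    pm: PropensityModel, pool: PoolComposition
) -> dict[str, float]:
    """Per-step incorporation fractions f_i = w_i x_i / sum w_j x_j."""
    raw = {s: pm.weights.get(s, 0.0) * x for s, x in pool.fractions.items()}
    z = sum(raw.values())
    if z <= 0:
        raise ValueError("all effective propensities are zero")
    return {s: v / z for s, v in raw.items()}


def fit_weights(
    observed: Mapping[str, float],
    pool: PoolComposition,
    extendability: Mapping[str, float] | None = None,
) -> PropensityModel:
    """Invert predict_step_fractions: w_i proportional to f_i / x_i.

    Exact algebraic inverse (round-trips through predict_step_fractions).
    Infeasible when a sugar is observed but absent from the pool.
    """
    f = {k: float(v) for k, v in observed.items()}
    if any(v < 0 for v in f.values()) or sum(f.values()) <= 0:
        raise ValueError("observed fractions must be >= 0 with positive sum")
    w = {}
    for s, fi in f.items():
        xi = pool.fractions.get(s, 0.0)
        if fi > 0 and xi == 0:
            raise ValueError(f"observed {s} incorporation with zero pool fraction")
        w[s] = 0.0 if fi == 0 else fi / xi
    z = sum(w.values())
    w = {s: v / z for s, v in w.items()}
    return PropensityModel(
        w, extendability if extendability is not None else dict(DEFAULT_EXTENDABILITY)
    )


def enumerate_products(
    pm: PropensityModel,
    pool: PoolComposition,
    depth: int,
    initial_terminal: str = "ribo",
) -> dict[tuple[str, ...], float]:
    """Exact distribution over added-sugar sequences up to ``depth``.

    The chain starts at a primer whose terminal sugar is
    ``initial_terminal``.  Before every addition the chain continues with
    probability e(current terminus); a sequence of length m < depth carries
    the explicit stop factor (1 - e(last sugar)).  Probabilities sum to 1,
    including the empty (never-extended) sequence.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    f = predict_step_fractions(pm, pool)
    sugars = list(f)
    dist: dict[tuple[str, ...], float] = {}

    def rec(seq: tuple[str, ...], prob: float) -> None:
        term = seq[-1] if seq else initial_terminal
        e = pm.e(term)
        if len(seq) == depth:
            dist[seq] = dist.get(seq, 0.0) + prob
            return
        # stop here
        if 1 - e > 0:
            dist[seq] = dist.get(seq, 0.0) + prob * (1 - e)
        if e > 0:
            for s in sugars:
                if f[s] > 0:
                    rec(seq + (s,), prob * e * f[s])

    rec((), 1.0)
    return dist


def conditional_full_depth(
    dist: Mapping[tuple[str, ...], float], depth: int
) -> dict[tuple[str, ...], float]:
    """Distribution conditioned on reaching the full depth."""
    full = {k: v for k, v in dist.items() if len(k) == depth}
    z = sum(full.values())
    if z == 0:
        raise ValueError(f"no probability mass at depth {depth}")
    return {k: v / z for k, v in full.items()}


def sample_chains(
    pm: PropensityModel,
    pool: PoolComposition,
    depth: int,
    n: int,
    seed: int,
    initial_terminal: str = "ribo",
) -> dict[tuple[str, ...], float]:
    """Monte-Carlo twin of enumerate_products (empirical frequencies)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    f = predict_step_fractions(pm, pool)
    sugars = list(f)
    probs = np.array([f[s] for s in sugars])
    counts: Counter[tuple[str, ...]] = Counter()
    for _ in range(n):
        seq: list[str] = []
        term = initial_terminal
        while len(seq) < depth:
            if rng.random() >= pm.e(term):
                break
            term = sugars[rng.choice(len(sugars), p=probs)]
            seq.append(term)
        counts[tuple(seq)] += 1
    return {k: v / n for k, v in counts.items()}


def total_variation(
    p: Mapping[tuple[str, ...], float], q: Mapping[tuple[str, ...], float]
) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
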