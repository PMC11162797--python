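"""File I/O for the CSV/JSON/YAML dialects the analysis consumes.

* gel time courses: CSV with columns ``replicate, t_hours, p_frac``
* species trajectories: tidy CSV ``time, species, mM`` (or wide)
* LC-MS compound lists: CSV ``replicate, neutral_mass_da, rt_min, abundance``
* oligomer specs: JSON ``{"residues": [...], "five_prime_end": ..., ...}``
* rate constants: YAML or JSON mapping of constant names
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .chemistry import OligomerSpec, oligomer_from_dict
from .lcms import CompoundRecord
from .network import RateConstants
from .rates import ExtensionTimeCourse

__all__ = [
    "read_gel_csv",
    "write_gel_csv",
    "read_compound_csv",
    "write_compound_csv",
    "read_oligomer_json",
    "read_rate_constants",
    "write_trajectory_csv",
]


def read_gel_csv(path) -> list[ExtensionTimeCourse]:
    df = pd.read_csv(path)
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        out.append(
            ExtensionTimeCourse(
                str(rep), tuple(grp["t_hours"]), tuple(grp["p_frac"])
            )
        )
    return out


def write_gel_csv(timecourses: Sequence[ExtensionTimeCourse], path) -> None:
    rows = [
        {"replicate": tc.replicate, "t_hours": t, "p_frac": p}
        for tc in timecourses
        for t, p in zip(tc.t, tc.p_frac)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_compound_csv(path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    return [
        CompoundRecord(
            neutral_mass=row.neutral_mass_da,
            retention_time=row.rt_min,
            abundance=row.abundance,
            replicate=str(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_compound_csv(records: Sequence[CompoundRecord], path) -> None:
    pd.DataFrame(
        {
            "replicate": [r.replicate for r in records],
            "neutral_mass_da": [r.neutral_mass for r in records],
            "rt_min": [r.retention_time for r in records],
            "abundance": [r.abundance for r in records],
        }
    ).to_csv(path, index=False)


def read_oligomer_json(path) -> OligomerSpec:
    with open(path) as fh:
        return oligomer_from_dict(json.load(fh))


def read_rate_constants(path) -> RateConstants:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RateConstants(**data)


def write_trajectory_csv(df: pd.DataFrame, path, tidy: bool = True) -> None:
    out = (
        df.melt(id_vars="time", var_name="species", value_name="mM")
        if tidy
        else df
    )
    out.to_csv(path, index=False)
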