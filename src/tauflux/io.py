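"""CSV readers and writers for the pipeline's table dialects.

All formats are plain long-form CSV so they survive spreadsheets and
version control:

* incubations: ``station, replicate, analyte, time_h, conc_nM, is_control``
* chambers: ``station, replicate, volume_L, n_individuals, total_biomass_gC``
* specimens: ``taxon, group, length_um, diameter_um, count``
* bottles: ``station, depth_m, tau_nM, doc_uM[, tdn_uM, no3_uM, no2_uM, nh4_uM]``
* turnover inputs: ``region, rr_c_nmol_ind_d, abundance_lo, abundance_hi,
  ambient_nM``
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError
from .morphometry import Specimen
from .release_rates import IncubationSeries

__all__ = [
    "read_incubations",
    "write_incubations",
    "read_chambers",
    "read_specimens",
    "write_specimens",
    "read_bottles",
    "read_turnover_inputs",
]

_INCUBATION_COLS = ["station", "replicate", "analyte", "time_h", "conc_nM", "is_control"]


def read_incubations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _INCUBATION_COLS[:5] if c not in df.columns]
    if missing:
        raise InvalidInputError(f"incubation table missing columns: {missing}")
    if "is_control" not in df.columns:
        df["is_control"] = False
    return df


def write_incubations(series: Iterable[IncubationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times_h, s.concs_nM):
            rows.append(
                {
                    "station": s.station,
                    "replicate": s.replicate,
                    "analyte": s.analyte,
                    "time_h": t,
                    "conc_nM": c,
                    "is_control": s.is_control,
                }
            )
    pd.DataFrame(rows, columns=_INCUBATION_COLS).to_csv(path, index=False)


def read_chambers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["station", "replicate", "volume_L", "n_individuals", "total_biomass_gC"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"chamber table missing columns: {missing}")
    return df


def read_specimens(path: str | Path) -> list[Specimen]:
    df = pd.read_csv(path)
    needed = ["taxon", "group", "length_um", "diameter_um"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"specimen table missing columns: {missing}")
    counts = df["count"] if "count" in df.columns else [1] * len(df)
    return [
        Specimen(str(t), str(g), float(L), float(d), int(n))
        for t, g, L, d, n in zip(
            df["taxon"], df["group"], df["length_um"], df["diameter_um"], counts
        )
    ]


def write_specimens(specimens: Sequence[Specimen], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "group": s.group,
                "length_um": s.length_um,
                "diameter_um": s.diameter_um,
                "count": s.count,
            }
            for s in specimens
        ]
    ).to_csv(path, index=False)


def read_bottles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("station", "depth_m", "tau_nM") if c not in df.columns]
    if missing:
        raise InvalidInputError(f"bottle table missing columns: {missing}")
    return df


def read_turnover_inputs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["region", "rr_c_nmol_ind_d", "abundance_lo", "abundance_hi", "ambient_nM"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"turnover table missing columns: {missing}")
    return df
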