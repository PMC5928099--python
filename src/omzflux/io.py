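"""Delimited-text readers/writers and the table schema registry.

All tables are UTF-8 delimited text (default comma) with a header row and
"." as the decimal mark.  Three schemas are registered:

``cells`` — one row per nanoSIMS region of interest
    cell_id (text), station (text), depth_m (m), length_A_um (µm),
    width_B_um (µm), r13C_12C (ratio), minor_counts (ion counts, int);
    optional: r15N14N (ratio), s_content (32S/(12C+13C) ratio),
    probe_positive (bool), true_* truth columns from the simulator.

``profile`` — tidy depth profiles, one row per (station, analyte, depth)
    station (text), depth_m (m), analyte (one of NO3, NO2, NH4, H2S, S0,
    S2O3, cells_SUP05, cells_total, rate_volumetric), value (µmol/L for
    chemistry, cells/L for counts, nmol/L/d for rates), unit (text).

``incubation`` — one row per exetainer timepoint
    station (text), depth_m (m), experiment (nitrate_15N | nitrite_15N |
    ammonium_15N | bicarbonate_13C), time_h (hours), labeled_fraction_F
    (dimensionless); optional channels excess_29N2, excess_30N2
    (nmol N2/L), excess_13C_POC (nmol C/L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .budget import Profile
from .incubation import IncubationSeries

__all__ = [
    "SCHEMAS",
    "UNITS",
    "Schema",
    "read_table",
    "write_table",
    "profiles_from_table",
    "profiles_to_table",
    "incubations_from_table",
    "incubations_to_table",
]

#: Unit strings attached to every numeric column written to reports.
UNITS = {
    "depth_m": "m",
    "length_A_um": "um",
    "width_B_um": "um",
    "r13C_12C": "ratio",
    "r15N14N": "ratio",
    "s_content": "ratio",
    "minor_counts": "counts",
    "time_h": "h",
    "labeled_fraction_F": "fraction",
    "excess_29N2": "nmol_N2/L",
    "excess_30N2": "nmol_N2/L",
    "excess_13C_POC": "nmol_C/L",
    "biovolume_um3": "um^3",
    "carbon_fg": "fg_C/cell",
    "carbon_fmol": "fmol_C/cell",
    "turnover_per_day": "1/d",
    "rate_fmol_per_day": "fmol_C/cell/d",
    "rate": "nmol/L/d",
    "se": "nmol/L/d",
    "detection_limit": "nmol/L/d",
    "gradient_mmol_m4": "mmol/m^3/m",
    "kz_m2_s": "m^2/s",
    "flux_mmol_m2_d": "mmol/m^2/d",
    "value": "per analyte (umol/L | cells/L | nmol/L/d)",
}

_ANALYTES = (
    "NO3", "NO2", "NH4", "H2S", "S0", "S2O3",
    "cells_SUP05", "cells_total", "rate_volumetric",
)


@dataclass(frozen=True)
class Schema:
    """Column contract for one table kind."""

    name: str
    required: dict  #: column -> kind ("text" | "numeric" | "int" | "bool")
    optional: dict
    sort_by: tuple = ()


SCHEMAS = {
    "cells": Schema(
        name="cells",
        required={
            "cell_id": "text",
            "station": "text",
            "depth_m": "numeric",
            "length_A_um": "numeric",
            "width_B_um": "numeric",
            "r13C_12C": "numeric",
            "minor_counts": "int",
        },
        optional={
            "r15N14N": "numeric",
            "s_content": "numeric",
            "probe_positive": "bool",
        },
    ),
    "profile": Schema(
        name="profile",
        required={
            "station": "text",
            "depth_m": "numeric",
            "analyte": "text",
            "value": "numeric",
            "unit": "text",
        },
        optional={},
        sort_by=("station", "analyte", "depth_m"),
    ),
    "incubation": Schema(
        name="incubation",
        required={
            "station": "text",
            "depth_m": "numeric",
            "experiment": "text",
            "time_h": "numeric",
            "labeled_fraction_F": "numeric",
        },
        optional={
            "replicate": "int",
            "excess_29N2": "numeric",
            "excess_30N2": "numeric",
            "excess_13C_POC": "numeric",
        },
    ),
}


def _coerce(df: pd.DataFrame, col: str, kind: str) -> pd.Series:
    s = df[col]
    if kind == "text":
        return s.astype(str)
    if kind == "bool":
        if s.dtype == bool:
            return s
        return s.astype(str).str.lower().isin(("true", "1", "yes"))
    coerced = pd.to_numeric(s, errors="coerce")
    bad = coerced.isna() & s.notna()
    if bad.any():
        # +2: header row plus 1-based numbering
        lines = [str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise ValueError(
            f"column {col!r}: non-numeric value(s) at line(s) {', '.join(lines)}"
        )
    if kind == "int":
        if not np.allclose(coerced.dropna() % 1, 0):
            raise ValueError(f"column {col!r}: expected integer counts")
        return coerced.astype("int64")
    return coerced.astype(float)


def read_table(path, schema_id: str, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a delimited-text table against a named schema.

    Missing required columns, non-numeric values (reported with line
    numbers) and unknown profile analytes are hard errors.  A profile
    table whose depths are not monotone within a (station, analyte) series
    is sorted automatically with a warning.
    """
    try:
        schema = SCHEMAS[schema_id]
    except KeyError:
        raise ValueError(
            f"unknown schema {schema_id!r}; choose from {sorted(SCHEMAS)}"
        ) from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {missing} "
            f"for schema {schema_id!r}"
        )
    for col, kind in schema.required.items():
        df[col] = _coerce(df, col, kind)
    for col, kind in schema.optional.items():
        if col in df.columns:
            df[col] = _coerce(df, col, kind)

    if schema_id == "profile":
        unknown = set(df["analyte"]) - set(_ANALYTES)
        if unknown:
            raise ValueError(f"{path.name}: unknown analyte(s) {sorted(unknown)}")
        nonmono = [
            key
            for key, grp in df.groupby(["station", "analyte"])
            if np.any(np.diff(grp["depth_m"].to_numpy()) < 0)
        ]
        if nonmono:
            warnings.warn(
                f"{path.name}: non-monotone depths for {nonmono}; sorting",
                stacklevel=2,
            )
        if schema.sort_by:
            df = df.sort_values(list(schema.sort_by), kind="stable").reset_index(
                drop=True
            )
    return df


def write_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a table as UTF-8 delimited text with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False)


def profiles_from_table(df: pd.DataFrame) -> list[Profile]:
    """Split a tidy profile table into one Profile per (station, analyte)."""
    out = []
    for (station, analyte), grp in df.groupby(["station", "analyte"], sort=True):
        grp = grp.sort_values("depth_m", kind="stable")
        if grp["depth_m"].duplicated().any():
            raise ValueError(
                f"duplicate depths in profile ({station}, {analyte})"
            )
        out.append(
            Profile(
                station=str(station),
                analyte=str(analyte),
                depths_m=grp["depth_m"].to_numpy(),
                values=grp["value"].to_numpy(),
                unit=str(grp["unit"].iloc[0]) if "unit" in grp else "umol/L",
            )
        )
    return out


def profiles_to_table(profiles) -> pd.DataFrame:
    """Tidy table (station, depth_m, analyte, value, unit) from Profiles."""
    frames = [
        pd.DataFrame(
            {
                "station": p.station,
                "depth_m": p.depths_m,
                "analyte": p.analyte,
                "value": p.values,
                "unit": p.unit,
            }
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


def incubations_from_table(df: pd.DataFrame) -> list[IncubationSeries]:
    """Assemble IncubationSeries from long-format exetainer rows."""
    out = []
    df = df.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0
    keys = ["station", "depth_m", "experiment", "labeled_fraction_F", "replicate"]
    for (station, depth, exp, F, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h", kind="stable")

        def channel(col: str):
            if col in grp.columns and grp[col].notna().any():
                return grp[col].to_numpy(dtype=float)
            return None

        out.append(
            IncubationSeries(
                experiment=str(exp),
                station=str(station),
                depth_m=float(depth),
                timepoints_h=grp["time_h"].to_numpy(dtype=float),
                labeled_fraction_F=float(F),
                replicate=int(rep),
                excess_29N2=channel("excess_29N2"),
                excess_30N2=channel("excess_30N2"),
                excess_13C_POC=channel("excess_13C_POC"),
            )
        )
    return out


def incubations_to_table(series_list) -> pd.DataFrame:
    """Long-format exetainer table from IncubationSeries objects."""
    frames = []
    for s in series_list:
        n = s.timepoints_h.size
        frames.append(
            pd.DataFrame(
                {
                    "station": s.station,
                    "depth_m": s.depth_m,
                    "experiment": s.experiment,
                    "time_h": s.timepoints_h,
                    "labeled_fraction_F": s.labeled_fraction_F,
                    "replicate": s.replicate,
                    "excess_29N2": s.excess_29N2 if s.excess_29N2 is not None else [np.nan] * n,
                    "excess_30N2": s.excess_30N2 if s.excess_30N2 is not None else [np.nan] * n,
                    "excess_13C_POC": s.excess_13C_POC if s.excess_13C_POC is not None else [np.nan] * n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
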