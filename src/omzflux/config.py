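"""Run configuration: a structured YAML file mapped onto one dataclass."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _default_flux_windows() -> dict:
    # Chemocline gradient windows (m): nitrate above, sulfide below,
    # elemental sulfur across the transition.
    return {"NO3": [12.0, 30.0], "H2S": [30.0, 40.0], "S0": [20.0, 30.0]}


def _default_sim() -> dict:
    return {
        "cells": {"n_cells": 200, "station": "U1"},
        "profiles": [
            {"analyte": "NO3", "surface_conc": 25.0, "bottom_conc": 0.0,
             "chemocline_depth": 30.0},
            {"analyte": "H2S", "surface_conc": 0.0, "bottom_conc": 7.0,
             "chemocline_depth": 33.0},
            {"analyte": "S0", "surface_conc": 0.0, "bottom_conc": 4.0,
             "chemocline_depth": 27.0},
            {"analyte": "cells_SUP05", "surface_conc": 1.0e8,
             "bottom_conc": 1.7e9, "chemocline_depth": 30.0, "noise_sd": 0.0},
            {"analyte": "rate_volumetric", "surface_conc": 100.0,
             "bottom_conc": 600.0, "chemocline_depth": 30.0, "noise_sd": 0.0},
        ],
        "incubation": {"true_denitrification": 10.0, "true_anammox": 2.0,
                       "labeled_fraction": 0.5, "n_replicates": 3},
        "depths": list(range(5, 66, 5)),
        "station": "U1",
    }


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    With ``simulate=True`` the synthetic generators produce the input
    tables (written under the output directory); otherwise the three
    ``*_path`` entries must point at existing delimited-text tables
    conforming to the registered schemas.
    """

    output_dir: str = "omzflux_out"
    seed: int = 0
    simulate: bool = True
    delimiter: str = ","
    cells_path: str | None = None
    profiles_path: str | None = None
    incubation_path: str | None = None
    # isotope context for the single-cell stage
    r_background: float = 0.0112
    r_dic: float | None = None  #: if None, derived from the spike recipe
    spike: dict = field(default_factory=dict)  #: kwargs for label_fraction()
    incubation_days: float = 1.0
    qc_threshold: float = 0.05
    biovolume_variant: str = "printed"
    # flux/budget parameters
    kz_m2_s: float = 1.4e-4
    flux_windows: dict = field(default_factory=_default_flux_windows)
    integration_window: list = field(default_factory=lambda: [30.0, 65.0])
    yields: list = field(default_factory=lambda: [0.35, 0.58])
    stoich_mode: str = "full_to_sulfate"
    alpha: float = 0.05
    percent_digits: int = 0
    # synthetic-data parameters
    sim: dict = field(default_factory=_default_sim)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate_inputs(self) -> None:
        """Fail fast if file inputs are required but absent."""
        if self.simulate:
            return
        missing = []
        for name in ("cells_path", "profiles_path", "incubation_path"):
            p = getattr(self, name)
            if p is None:
                missing.append(f"{name} is not set")
            elif not Path(p).exists():
                missing.append(f"{name}={p!r} does not exist")
        if missing:
            raise ValueError(
                "simulate=false requires input tables: " + "; ".join(missing)
            )
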