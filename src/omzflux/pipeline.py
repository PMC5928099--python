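"""End-to-end pipeline: simulate -> cells -> rates -> flux -> budget.

Each stage reads/writes the registered delimited-text schemas so that
stages can also be run individually from the command line.  A run is fully
determined by its config and seed: identical inputs produce byte-identical
outputs, recorded in a manifest (config hash, seed, package version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, budget, incubation, io, singlecell, synthetic
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_inputs"]

ALL_STAGES = ("cells", "rates", "flux", "budget")


def _isotope_context(cfg: RunConfig) -> singlecell.IsotopeContext:
    r_dic = cfg.r_dic
    if r_dic is None:
        r_dic = singlecell.label_fraction(**cfg.spike).r_dic
    return singlecell.IsotopeContext(
        r_dic=r_dic,
        incubation_days=cfg.incubation_days,
        r_background=cfg.r_background,
    )


def simulate_inputs(cfg: RunConfig, out_dir: Path) -> dict:
    """Generate the three input tables from the config's sim block.

    Seeds for the individual generators are derived deterministically from
    the run seed.  Returns the paths written, and points the config's
    input paths at them so downstream stages are source-agnostic.
    """
    sim = cfg.sim
    ss = np.random.SeedSequence(cfg.seed)
    cell_seed, prof_seed, inc_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    ctx = _isotope_context(cfg)
    cell_kwargs = dict(sim.get("cells", {}))
    cell_kwargs.setdefault("station", sim.get("station", "SYN"))
    cells = synthetic.gen_cells(
        synthetic.CellSimParams(
            seed=cell_seed,
            r_background=ctx.r_background,
            r_dic=ctx.r_dic,
            incubation_days=ctx.incubation_days,
            **cell_kwargs,
        )
    )
    cells_path = inputs / "cells.csv"
    io.write_table(cells, cells_path, cfg.delimiter)

    depths = tuple(sim.get("depths", tuple(range(5, 66, 5))))
    profiles = []
    for i, spec in enumerate(sim.get("profiles", [])):
        params = synthetic.ProfileSimParams(
            depths=depths,
            station=sim.get("station", "SYN"),
            seed=prof_seed + i,
            **spec,
        )
        profiles.append(synthetic.gen_profile(params))
    profiles_path = inputs / "profiles.csv"
    io.write_table(io.profiles_to_table(profiles), profiles_path, cfg.delimiter)

    inc_kwargs = dict(sim.get("incubation", {}))
    series = synthetic.gen_incubation(
        synthetic.IncubationSimParams(
            seed=inc_seed, station=sim.get("station", "SYN"), **inc_kwargs
        )
    )
    incubation_path = inputs / "incubation.csv"
    io.write_table(io.incubations_to_table(series), incubation_path, cfg.delimiter)

    cfg.cells_path = str(cells_path)
    cfg.profiles_path = str(profiles_path)
    cfg.incubation_path = str(incubation_path)
    return {
        "cells": str(cells_path),
        "profiles": str(profiles_path),
        "incubation": str(incubation_path),
    }


def _stage_cells(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    cells = io.read_table(cfg.cells_path, "cells", cfg.delimiter)
    ctx = _isotope_context(cfg)
    results = singlecell.process_cells(
        cells, ctx, variant=cfg.biovolume_variant, qc_threshold=cfg.qc_threshold
    )
    io.write_table(results, out_dir / "cell_rates.csv", cfg.delimiter)
    summary = singlecell.station_summary(results)
    io.write_table(summary, out_dir / "station_summary.csv", cfg.delimiter)
    return results


def _stage_rates(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    table = io.read_table(cfg.incubation_path, "incubation", cfg.delimiter)
    series_list = io.incubations_from_table(table)
    rows = []
    for s in series_list:
        if s.excess_29N2 is not None and s.excess_30N2 is not None:
            den, amx = incubation.pairing_rates(s, alpha=cfg.alpha)
            for process, r in (("denitrification", den), ("anammox", amx)):
                rows.append(
                    dict(
                        station=s.station, depth_m=s.depth_m,
                        experiment=s.experiment, replicate=s.replicate,
                        process=process, **asdict(r),
                    )
                )
        if s.excess_13C_POC is not None:
            rate = incubation.bulk_c_fixation(s, method="endpoint")
            rows.append(
                dict(
                    station=s.station, depth_m=s.depth_m,
                    experiment=s.experiment, replicate=s.replicate,
                    process="c_fixation", rate=rate, se=np.nan,
                    p_value=np.nan, significant=True, df=0,
                    detection_limit=np.nan,
                )
            )
    rates = pd.DataFrame(rows)
    # campaign detection limit per process, from the slope SEs
    for process, grp in rates.groupby("process"):
        ses = grp["se"].dropna()
        if len(ses) and (grp["df"] > 0).any():
            df_mode = int(grp.loc[grp["df"] > 0, "df"].mode().iloc[0])
            dl = incubation.detection_limit(ses, alpha=cfg.alpha, df=df_mode)
            rates.loc[rates["process"] == process, "detection_limit"] = dl
    io.write_table(rates, out_dir / "incubation_rates.csv", cfg.delimiter)
    return rates


def _stage_flux(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    table = io.read_table(cfg.profiles_path, "profile", cfg.delimiter)
    profiles = {p.analyte: p for p in io.profiles_from_table(table)}
    rows = []
    for analyte, window in cfg.flux_windows.items():
        if analyte not in profiles:
            logger.warning("no profile for analyte %s; skipping flux", analyte)
            continue
        est = budget.estimate_flux(
            profiles[analyte], window[0], window[1], kz_m2_s=cfg.kz_m2_s
        )
        rows.append(asdict(est))
    fluxes = pd.DataFrame(rows)
    io.write_table(fluxes, out_dir / "fluxes.csv", cfg.delimiter)
    return fluxes


def _stage_budget(
    cfg: RunConfig,
    out_dir: Path,
    cell_results: pd.DataFrame,
    fluxes: pd.DataFrame,
) -> dict:
    table = io.read_table(cfg.profiles_path, "profile", cfg.delimiter)
    profiles = {p.analyte: p for p in io.profiles_from_table(table)}
    flux_by_analyte = (
        dict(zip(fluxes["analyte"], fluxes["flux_mmol_m2_d"]))
        if len(fluxes)
        else {}
    )

    out: dict = {"units": {}}
    model = budget.StoichiometryModel()
    ylo, yhi = cfg.yields
    yields = budget.YieldModel(ylo, yhi, stoichiometry=model)

    if "H2S" in flux_by_analyte and "NO3" in flux_by_analyte:
        demand = budget.nitrate_demand(
            flux_by_analyte["H2S"],
            s0_flux=flux_by_analyte.get("S0", 0.0),
            model=model,
            mode=cfg.stoich_mode,
        )
        no3_flux = flux_by_analyte["NO3"]
        out["nitrate_demand_mmol_m2_d"] = demand
        out["nitrate_flux_mmol_m2_d"] = no3_flux
        if no3_flux > 0:
            out["percent_no3_to_sulfide"] = budget.percent_attribution(
                demand, no3_flux
            )

    summary = singlecell.station_summary(cell_results)
    if len(summary):
        per_cell = float(summary["rate_product"].iloc[0])
        out["per_cell_rate_fmol_d"] = per_cell
        if "cells_SUP05" in profiles:
            dens = profiles["cells_SUP05"]
            vol = budget.Profile(
                station=dens.station,
                analyte="rate_volumetric",
                depths_m=dens.depths_m,
                values=np.array(
                    [budget.volumetric_rate(per_cell, d) for d in dens.values]
                ),
                unit="nmol/L/d",
            )
            z0, z1 = cfg.integration_window
            out["sup05_integrated_mmol_m2_d"] = budget.depth_integrate(vol, z0, z1)
            out["mean_volumetric_nmol_l_d"] = float(np.mean(vol.values))
            if "rate_volumetric" in profiles:
                bulk_int = budget.depth_integrate(
                    profiles["rate_volumetric"], z0, z1
                )
                out["bulk_integrated_mmol_m2_d"] = bulk_int
                out["percent_dark_cfix_by_population"] = (
                    budget.percent_contribution(
                        out["sup05_integrated_mmol_m2_d"],
                        bulk_int,
                        digits=cfg.percent_digits,
                    )
                )
            dn_lo, dn_hi = budget.yield_convert(
                out["mean_volumetric_nmol_l_d"], yields, "denitrification"
            )
            sox_lo, sox_hi = budget.yield_convert(
                out["mean_volumetric_nmol_l_d"], yields, "s0_oxidation"
            )
            out["denitrification_interval_nmol_l_d"] = [dn_lo, dn_hi]
            out["s_oxidation_interval_nmol_l_d"] = [sox_lo, sox_hi]

    _write_budget_summary(out_dir / "budget_summary.txt", out, fluxes)
    return out


_SUMMARY_UNITS = {
    "nitrate_demand_mmol_m2_d": "mmol m^-2 d^-1",
    "nitrate_flux_mmol_m2_d": "mmol m^-2 d^-1",
    "percent_no3_to_sulfide": "%",
    "per_cell_rate_fmol_d": "fmol C cell^-1 d^-1",
    "mean_volumetric_nmol_l_d": "nmol C L^-1 d^-1",
    "sup05_integrated_mmol_m2_d": "mmol C m^-2 d^-1",
    "bulk_integrated_mmol_m2_d": "mmol C m^-2 d^-1",
    "percent_dark_cfix_by_population": "%",
    "denitrification_interval_nmol_l_d": "nmol N L^-1 d^-1",
    "s_oxidation_interval_nmol_l_d": "nmol S L^-1 d^-1",
}


def _write_budget_summary(path: Path, out: dict, fluxes: pd.DataFrame) -> None:
    lines = ["# Chemocline budget summary", ""]
    lines.append("## Flux-gradient estimates (positive downward)")
    for _, row in fluxes.iterrows():
        lines.append(
            f"  {row['analyte']:>6}: {row['flux_mmol_m2_d']:+.3f} mmol m^-2 d^-1 "
            f"(gradient {row['gradient_mmol_m4']:+.4f} mmol m^-3 m^-1 over "
            f"{row['z_top_m']:.0f}-{row['z_bottom_m']:.0f} m, "
            f"Kz {row['kz_m2_s']:.2e} m^2 s^-1)"
        )
    lines.append("")
    lines.append("## Budget and upscaling")
    for key, val in out.items():
        if key == "units":
            continue
        unit = _SUMMARY_UNITS.get(key, "")
        if isinstance(val, list):
            lines.append(f"  {key}: {val[0]:.3g} to {val[1]:.3g} {unit}")
        else:
            lines.append(f"  {key}: {val:.4g} {unit}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(cfg: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns a dict with the in-memory stage products.  Any stage failure
    is re-raised annotated with the stage name.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if cfg.simulate:
        results["inputs"] = simulate_inputs(cfg, out_dir)
    else:
        cfg.validate_inputs()

    cell_results = pd.DataFrame()
    fluxes = pd.DataFrame()
    for stage in stages:
        try:
            if stage == "cells":
                cell_results = _stage_cells(cfg, out_dir)
                results["cells"] = cell_results
            elif stage == "rates":
                results["rates"] = _stage_rates(cfg, out_dir)
            elif stage == "flux":
                fluxes = _stage_flux(cfg, out_dir)
                results["flux"] = fluxes
            elif stage == "budget":
                results["budget"] = _stage_budget(
                    cfg, out_dir, cell_results, fluxes
                )
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "omzflux",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(stages),
        "outputs": sorted(p.name for p in out_dir.glob("*.csv"))
        + ["budget_summary.txt"],
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    results["manifest"] = manifest
    return results
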