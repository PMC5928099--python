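"""Single-cell carbon-fixation calculus for nanoSIMS ROI measurements.

Converts per-cell rod dimensions and stable-isotope ratios into cell-specific
CO2 fixation rates for chemolithoautotrophic bacteria (here: SUP05-clade
sulfur oxidizers in oxygen-minimum-zone waters):

1. biovolume from rod length/diameter (rounded-rod formula),
2. allometric biovolume -> carbon content (fg C per cell = 135 V^0.438),
3. isotope-ratio excess -> fraction of cell carbon fixed per day,
4. rate = turnover x carbon content (fmol C per cell per day),

plus Poisson counting-statistics QC, per-group sulfur-content summaries,
one-way ANOVA between stations, and bookkeeping for the 13C-bicarbonate
spike that sets the labelling strength of the DIC pool.

All ratio arguments are minor/major ion-count ratios (e.g. 13C/12C) as
exported per region of interest by nanoSIMS post-processing software such
as Look@NanoSIMS; no ion-image handling happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NATURAL_13C_12C",
    "CARBON_ATOMIC_MASS",
    "IsotopeContext",
    "SpikeResult",
    "AnovaResult",
    "biovolume",
    "carbon_content",
    "fraction_fixed",
    "cell_rate",
    "poisson_qc",
    "sulfur_summary",
    "compare_groups",
    "label_fraction",
    "process_cells",
    "station_summary",
]

#: Natural-abundance 13C/12C ratio used as the unlabelled-cell background.
NATURAL_13C_12C = 0.0112

#: Standard atomic weight of carbon (g/mol), for fg <-> fmol conversion.
CARBON_ATOMIC_MASS = 12.011

# Rounded-rod biovolume V = pi * B^2 * (c1*A - c2*B).
# "printed" uses the published coefficient pair (0.125, 0.0833); note that at
# A == B it does NOT reduce to a sphere.  "geometric" is the exact capsule
# (cylinder of length A-B plus two hemispherical caps): pi B^2 (A/4 - B/12),
# which does satisfy the sphere limit.  See docs/methods.md.
_BIOVOLUME_COEFS = {
    "printed": (0.125, 0.0833),
    "geometric": (0.25, 0.0833),
}

_SALT_MOLAR_MASS_G_MOL = {
    # 13C-labelled bicarbonate salts: one 13C (13.00335) per formula unit.
    "sodium_bicarbonate": 22.9898 + 1.0079 + 13.00335 + 3 * 15.9994,  # ~85.0
    "potassium_bicarbonate": 39.0983 + 1.0079 + 13.00335 + 3 * 15.9994,
}


@dataclass(frozen=True)
class IsotopeContext:
    """Labelling context shared by all cells of one incubation.

    Parameters
    ----------
    r_dic : float
        13C/12C ratio of the labelled dissolved-inorganic-carbon pool
        (dimensionless); must exceed ``r_background``.
    incubation_days : float
        Incubation time in days (> 0).
    r_background : float
        13C/12C ratio of unlabelled cell material; defaults to natural
        abundance (0.0112).
    """

    r_dic: float
    incubation_days: float = 1.0
    r_background: float = NATURAL_13C_12C

    def __post_init__(self) -> None:
        if self.incubation_days <= 0:
            raise ValueError("incubation_days must be > 0")
        if self.r_dic <= 0:
            raise ValueError("r_dic must be > 0")
        if self.r_dic <= self.r_background:
            raise ValueError("r_dic must exceed r_background (labelled pool)")


@dataclass(frozen=True)
class SpikeResult:
    """Outcome of a 13C-bicarbonate spike calculation (per litre of bottle)."""

    added_13c_mmol_per_l: float
    label_fraction: float  #: added (excess) 13C over total DIC, dimensionless
    r_dic: float  #: 13C/12C ratio of the spiked DIC pool (incl. natural 13C)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    n_groups: int
    n_total: int


def biovolume(length_A_um, width_B_um, variant: str = "printed"):
    """Biovolume (um^3) of a rounded rod of length A and diameter B.

    ``variant="printed"`` evaluates pi*B^2*(0.125A - 0.0833B); the
    ``"geometric"`` capsule variant uses 0.25 in place of 0.125 and
    reduces to a sphere of diameter B when A == B.
    """
    try:
        c1, c2 = _BIOVOLUME_COEFS[variant]
    except KeyError:
        raise ValueError(
            f"unknown biovolume variant {variant!r}; "
            f"choose from {sorted(_BIOVOLUME_COEFS)}"
        ) from None
    A = np.asarray(length_A_um, dtype=float)
    B = np.asarray(width_B_um, dtype=float)
    if np.any(B <= 0):
        raise ValueError("width_B_um must be > 0")
    if np.any(A < B):
        raise ValueError("length_A_um must be >= width_B_um (rounded rod)")
    V = np.pi * B**2 * (c1 * A - c2 * B)
    return V if V.ndim else float(V)

def carbon_content(volume_um3, atomic_mass: float = CARBON_ATOMIC_MASS):
    """Cellular carbon from biovolume via the allometric power law.

    Returns ``(carbon_fg, carbon_fmol)`` with carbon_fg = 135 * V**0.438.
    The sub-linear exponent encodes that small cells carry more carbon per
    unit volume than large ones.
    """
    V = np.asarray(volume_um3, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volume_um3 must be > 0")
    fg = 135.0 * V**0.438
    fmol = fg / atomic_mass
    if fg.ndim:
        return fg, fmol
    return float(fg), float(fmol)


def fraction_fixed(r_cell, ctx: IsotopeContext, mode: str = "ratio"):
    """Fraction of cell carbon fixed per day from the cell 13C/12C ratio.

    ``mode="ratio"`` is the linear form
    ``f = (r_cell - r_background) / r_dic / t``,
    valid at low enrichment and used by default.  ``mode="atom_fraction"``
    first converts ratios r to atom fractions a = r/(1+r) and computes
    ``f = (a_cell - a_background) / (a_dic - a_background) / t``.

    Negative excesses (cell ratio below background) propagate through as
    negative turnovers; they are flagged downstream, never clipped, so that
    population means stay unbiased.
    """
    r = np.asarray(r_cell, dtype=float)
    t = ctx.incubation_days
    if mode == "ratio":
        f = (r - ctx.r_background) / ctx.r_dic / t
    elif mode == "atom_fraction":
        a_cell = r / (1.0 + r)
        a_bg = ctx.r_background / (1.0 + ctx.r_background)
        a_dic = ctx.r_dic / (1.0 + ctx.r_dic)
        f = (a_cell - a_bg) / (a_dic - a_bg) / t
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'ratio' or 'atom_fraction'")
    return f if f.ndim else float(f)


def cell_rate(f_per_day, carbon_fmol):
    """Cell-specific C fixation rate: turnover x carbon content (fmol/cell/d)."""
    carbon = np.asarray(carbon_fmol, dtype=float)
    if np.any(carbon <= 0):
        raise ValueError("carbon_fmol must be > 0")
    r = np.asarray(f_per_day, dtype=float) * carbon
    return r if r.ndim else float(r)


def poisson_qc(minor_counts, threshold: float = 0.05):
    """Counting-statistics quality check on the minor-isotope ion count.

    A measurement passes iff its relative Poisson error sqrt(N)/N is
    strictly below ``threshold`` (default 5%); N = 0 always fails.
    """
    N = np.asarray(minor_counts, dtype=float)
    if np.any(N < 0):
        raise ValueError("minor_counts must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(N > 0, np.sqrt(N) / np.where(N > 0, N, 1.0), np.inf)
    ok = rel < threshold
    return ok if ok.ndim else bool(ok)


def sulfur_summary(
    cells: pd.DataFrame,
    value_col: str = "s_content",
    by=("station", "depth_m"),
) -> pd.DataFrame:
    """Per-group summary of normalized single-cell sulfur content.

    Reports n, mean, median and the 5th/95th percentiles of the
    32S/(12C+13C) ratio per station-depth group (the box-plot convention
    used for such data).  Cells with a non-finite or negative ratio (e.g.
    zero carbon signal) are excluded with a warning; groups left empty are
    skipped with a warning.
    """
    by = list(by)
    bad = ~np.isfinite(cells[value_col]) | (cells[value_col] < 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} cell(s) with invalid {value_col}",
            stacklevel=2,
        )
    kept = cells.loc[~bad]
    rows = []
    for keys, grp in kept.groupby(by, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(
                zip(by, keys),
                n=vals.size,
                mean=float(np.mean(vals)),
                median=float(np.median(vals)),
                p05=float(np.percentile(vals, 5)),
                p95=float(np.percentile(vals, 95)),
            )
        )
    skipped = cells.loc[bad].groupby(by).size().index.difference(
        kept.groupby(by).size().index
    )
    if len(skipped):
        warnings.warn(f"skipped empty group(s): {list(skipped)}", stacklevel=2)
    return pd.DataFrame(rows)


def compare_groups(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-cell rates between stations.

    Requires at least two groups with at least two cells each.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups for ANOVA")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    F, p = stats.f_oneway(*samples)
    # identical groups yield 0/0; report F = 0 (no between-group variance)
    if not np.isfinite(F):
        between = np.var([np.mean(s) for s in samples])
        if between == 0:
            F, p = 0.0, 1.0
    return AnovaResult(float(F), float(p), len(samples), int(values.size))


def label_fraction(
    spike_mass_g: float = 1.0,
    spike_stock_ml: float = 50.0,
    aliquot_ml: float = 4.5,
    bottle_l: float = 4.5,
    ambient_dic_mm: float = 2.2,
    salt: str = "sodium_bicarbonate",
    r_background: float = NATURAL_13C_12C,
) -> SpikeResult:
    """13C labelling strength of the DIC pool from the spike recipe.

    The default arguments encode the standard shipboard recipe: 1 g of
    13C-bicarbonate dissolved in 50 mL, of which 4.5 mL is added to a
    4.5 L incubation bottle over an ambient DIC pool of 2.2 mM.

    Returns the added 13C (mmol per litre of bottle), the label fraction
    (13C over total DIC) and the 13C/12C ratio of the spiked pool, which is
    what the turnover equation consumes.  ``aliquot_ml = 0`` recovers the
    natural background ratio.
    """
    for name, val in [
        ("spike_mass_g", spike_mass_g),
        ("spike_stock_ml", spike_stock_ml),
        ("bottle_l", bottle_l),
        ("ambient_dic_mm", ambient_dic_mm),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be > 0")
    if aliquot_ml < 0:
        raise ValueError("aliquot_ml must be >= 0")
    try:
        molar_mass = _SALT_MOLAR_MASS_G_MOL[salt]
    except KeyError:
        raise ValueError(
            f"unknown salt {salt!r}; choose from {sorted(_SALT_MOLAR_MASS_G_MOL)}"
        ) from None
    added_mol = spike_mass_g * (aliquot_ml / spike_stock_ml) / molar_mass
    added_mmol_l = added_mol / bottle_l * 1000.0
    ambient_12c = ambient_dic_mm / (1.0 + r_background)
    ambient_13c = ambient_dic_mm - ambient_12c
    r_dic = (ambient_13c + added_mmol_l) / ambient_12c
    frac = added_mmol_l / (ambient_dic_mm + added_mmol_l)
    return SpikeResult(added_mmol_l, frac, r_dic)


def process_cells(
    cells: pd.DataFrame,
    ctx: IsotopeContext,
    variant: str = "printed",
    qc_threshold: float = 0.05,
    mode: str = "ratio",
    atomic_mass: float = CARBON_ATOMIC_MASS,
) -> pd.DataFrame:
    """Full per-cell pipeline: dimensions + isotope ratio -> fixation rate.

    Returns the input table augmented with ``biovolume_um3``, ``carbon_fg``,
    ``carbon_fmol``, ``turnover_per_day``, ``rate_fmol_per_day``,
    ``qc_pass`` and ``negative_turnover``.  Rates of QC-failing cells are
    computed but should be filtered on ``qc_pass`` for reporting.
    """
    out = cells.copy()
    V = biovolume(
        out["length_A_um"].to_numpy(),
        out["width_B_um"].to_numpy(),
        variant=variant,
    )
    fg, fmol = carbon_content(V, atomic_mass=atomic_mass)
    f = fraction_fixed(out["r13C_12C"].to_numpy(), ctx, mode=mode)
    out["biovolume_um3"] = V
    out["carbon_fg"] = fg
    out["carbon_fmol"] = fmol
    out["turnover_per_day"] = f
    out["rate_fmol_per_day"] = cell_rate(f, fmol)
    out["qc_pass"] = poisson_qc(out["minor_counts"].to_numpy(), qc_threshold)
    out["negative_turnover"] = f < 0
    return out


def station_summary(results: pd.DataFrame, qc_only: bool = True) -> pd.DataFrame:
    """Per-station aggregation of processed cells.

    Provides both published aggregation conventions:

    - ``rate_product``: mean turnover x mean carbon content (the form under
      which the published per-station means are mutually consistent), and
    - ``rate_percell_mean``: the plain mean of per-cell rates,

    together with standard errors of the per-cell rates.
    """
    df = results[results["qc_pass"]] if qc_only else results
    rows = []
    for station, grp in df.groupby("station", sort=True):
        n = len(grp)
        mean_f = float(grp["turnover_per_day"].mean())
        mean_c = float(grp["carbon_fmol"].mean())
        rates = grp["rate_fmol_per_day"].to_numpy(dtype=float)
        rows.append(
            {
                "station": station,
                "n_cells": n,
                "mean_biovolume_um3": float(grp["biovolume_um3"].mean()),
                "mean_carbon_fmol": mean_c,
                "mean_turnover_per_day": mean_f,
                "rate_product": mean_f * mean_c,
                "rate_percell_mean": float(rates.mean()),
                "rate_percell_se": float(
                    rates.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
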