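"""Synthetic inputs with the statistical structure the estimators assume.

Each generator is the exact inverse of its matching estimator, records the
simulated truth alongside the noisy observables (truth columns/fields are
prefixed ``true_``), and is fully reproducible for a fixed seed.  With all
noise switched off, generator -> estimator round trips recover the truth
to machine precision; that property is the backbone of the test suite.

Emulated structure:

- single cells: lognormal rod dimensions (positivity-preserving for sizes
  reported as mean +/- sd), lognormal per-cell fixation rates, cell
  13C/12C ratio = background + f * t * r_dic, Poisson noise on the
  minor-isotope ion count only (the 13C count dominates ratio uncertainty);
- depth profiles: logistic (sigmoidal) chemocline transition between
  surface and bottom end-members, additive Gaussian noise truncated at 0;
- incubation series: linear label accumulation with excess-30N2 slope
  D*F^2 and excess-29N2 slope A*F + 2F(1-F)*D, homoscedastic Gaussian
  noise per timepoint.

Not emulated: nanoSIMS instrument physics (sputtering, drift, matrix
effects), 2-D ion images, bottle/contamination artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budget import Profile
from .incubation import HOURS_PER_DAY, IncubationSeries
from .singlecell import (
    NATURAL_13C_12C,
    IsotopeContext,
    biovolume,
    carbon_content,
    label_fraction,
)

__all__ = [
    "DEFAULT_R_DIC",
    "PAPER_TIMEPOINTS_H",
    "CellSimParams",
    "ProfileSimParams",
    "IncubationSimParams",
    "gen_cells",
    "gen_profile",
    "gen_incubation",
    "gen_c_series",
]

#: 13C/12C ratio of the spiked DIC pool under the standard shipboard recipe
#: (1 g 13C-bicarbonate in 50 mL stock, 4.5 mL into a 4.5 L bottle over
#: 2.2 mM ambient DIC) — the default labelling strength for simulations.
DEFAULT_R_DIC = label_fraction().r_dic

#: Exetainer termination times of the incubation design (hours).
PAPER_TIMEPOINTS_H = (0.0, 6.0, 12.0, 24.0, 48.0)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int):
    """Lognormal draws parameterized by arithmetic mean and CV; cv=0 is exact."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _require_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not val > 0:
            raise ValueError(f"{name} must be > 0 (got {val!r})")


@dataclass
class CellSimParams:
    """Simulation parameters for a single-cell nanoSIMS experiment.

    Defaults reproduce the shelf-station study conditions: mean per-cell
    rate 0.19 fmol C cell^-1 d^-1, rod dimensions giving a mean biovolume
    near 0.18 µm^3, a 24-h incubation, and the recipe-derived DIC
    labelling ratio.  ``counting_noise=False`` switches off the Poisson
    ion-count noise for exact round-trip tests.
    """

    n_cells: int = 100
    true_rate_mean: float = 0.19  #: fmol C per cell per day
    true_rate_cv: float = 0.3
    length_mean_um: float = 1.4
    width_mean_um: float = 0.7
    size_cv: float = 0.2
    r_background: float = NATURAL_13C_12C
    r_dic: float = DEFAULT_R_DIC
    incubation_days: float = 1.0
    mean_minor_counts: float = 1e4  #: expected 13C ion counts per ROI
    counting_noise: bool = True
    s_content_mean: float = 0.1  #: mean 32S/(12C+13C) ratio
    s_content_cv: float = 0.3
    station: str = "SYN"
    depth_m: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_cells, (int, np.integer)) or self.n_cells < 1:
            raise ValueError(f"n_cells must be a positive integer (got {self.n_cells!r})")
        _require_positive(
            length_mean_um=self.length_mean_um,
            width_mean_um=self.width_mean_um,
            r_background=self.r_background,
            r_dic=self.r_dic,
            incubation_days=self.incubation_days,
            mean_minor_counts=self.mean_minor_counts,
            s_content_mean=self.s_content_mean,
        )
        if self.true_rate_mean < 0:
            raise ValueError("true_rate_mean must be >= 0")
        for name in ("true_rate_cv", "size_cv", "s_content_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.width_mean_um > self.length_mean_um:
            raise ValueError("width_mean_um must not exceed length_mean_um")
        if self.r_dic <= self.r_background:
            raise ValueError("r_dic must exceed r_background")

    @property
    def context(self) -> IsotopeContext:
        return IsotopeContext(
            r_dic=self.r_dic,
            incubation_days=self.incubation_days,
            r_background=self.r_background,
        )


@dataclass
class ProfileSimParams:
    """Simulation parameters for one chemocline-shaped depth profile.

    ``shape="logistic"`` draws a sigmoidal transition from ``surface_conc``
    to ``bottom_conc`` centred at ``chemocline_depth`` with e-folding
    half-width ``chemocline_width``; ``shape="linear"`` is the degenerate
    infinite-width limit, a straight ramp across the sampled range (its
    gradient is exactly recoverable, which anchors the flux tests).
    """

    depths: tuple = tuple(range(5, 61, 5))
    chemocline_depth: float = 30.0
    chemocline_width: float = 3.0
    analyte: str = "NO3"
    surface_conc: float = 25.0  #: µmol/L end-member above the chemocline
    bottom_conc: float = 0.0
    noise_sd: float = 0.5  #: µmol/L
    shape: str = "logistic"
    station: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        self.depths = tuple(float(z) for z in self.depths)
        # YAML-sourced numbers may arrive as strings (e.g. "1.0e8")
        for name in ("chemocline_depth", "chemocline_width", "surface_conc",
                     "bottom_conc", "noise_sd"):
            setattr(self, name, float(getattr(self, name)))
        if len(self.depths) < 3:
            raise ValueError("need at least 3 depths (gradient fitting downstream)")
        if any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if min(self.depths) <= 0:
            raise ValueError("depths must be positive (metres below surface)")
        _require_positive(chemocline_depth=self.chemocline_depth,
                          chemocline_width=self.chemocline_width)
        if self.surface_conc < 0 or self.bottom_conc < 0:
            raise ValueError("end-member concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shape not in ("logistic", "linear"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class IncubationSimParams:
    """Simulation parameters for 15N-labelled incubation experiments."""

    timepoints: tuple = PAPER_TIMEPOINTS_H  #: hours
    true_denitrification: float = 10.0  #: nmol N per L per day
    true_anammox: float = 2.0  #: nmol N per L per day
    labeled_fraction: float = 0.5
    noise_sd: float = 0.5  #: nmol N per L, per timepoint
    n_replicates: int = 1
    station: str = "SYN"
    depth_m: float = 30.0
    experiment: str = "nitrate_15N"
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (0.0 < self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must lie in (0, 1]")
        if self.true_denitrification < 0 or self.true_anammox < 0:
            raise ValueError("true rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")


def gen_cells(params: CellSimParams) -> pd.DataFrame:
    """Generate a table of synthetic nanoSIMS cell measurements.

    Inverse of the single-cell rate calculus: per-cell true rates are
    converted through the biovolume/carbon pipeline into the isotope ratio
    a noise-free instrument would report, then Poisson counting noise is
    applied to the minor-isotope count (the major count is treated as
    exact).  Truth columns are prefixed ``true_``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells

    length = _lognormal(rng, params.length_mean_um, params.size_cv, n)
    width = _lognormal(rng, params.width_mean_um, params.size_cv, n)
    width = np.minimum(width, length)  # rod invariant: width <= length

    V = biovolume(length, width)
    _, carbon_fmol = carbon_content(V)

    true_rate = _lognormal(rng, params.true_rate_mean, params.true_rate_cv, n) \
        if params.true_rate_mean > 0 else np.zeros(n)
    true_f = true_rate / carbon_fmol
    r_true = params.r_background + true_f * params.incubation_days * params.r_dic

    expected_minor = np.full(n, params.mean_minor_counts)
    if params.counting_noise:
        minor = rng.poisson(expected_minor).astype(float)
        r_obs = r_true * minor / expected_minor
        minor_counts = minor.astype(int)
    else:
        r_obs = r_true
        minor_counts = np.round(expected_minor).astype(int)

    s_content = _lognormal(rng, params.s_content_mean, params.s_content_cv, n)

    return pd.DataFrame(
        {
            "cell_id": [f"{params.station}_c{i:05d}" for i in range(n)],
            "station": params.station,
            "depth_m": params.depth_m,
            "length_A_um": length,
            "width_B_um": width,
            "r13C_12C": r_obs,
            "r15N14N": np.nan,
            "s_content": s_content,
            "minor_counts": minor_counts,
            "probe_positive": True,
            "true_rate_fmol_per_day": true_rate,
            "true_turnover_per_day": true_f,
            "true_biovolume_um3": V,
            "true_carbon_fmol": carbon_fmol,
            "true_r13C_12C": r_true,
        }
    )


def gen_profile(params: ProfileSimParams) -> Profile:
    """Generate one synthetic depth profile with a chemocline transition."""
    rng = np.random.default_rng(params.seed)
    z = np.asarray(params.depths)
    if params.shape == "linear":
        conc = np.interp(
            z, [z[0], z[-1]], [params.surface_conc, params.bottom_conc]
        )
    else:
        s = 1.0 / (1.0 + np.exp(-(z - params.chemocline_depth) / params.chemocline_width))
        conc = params.surface_conc + (params.bottom_conc - params.surface_conc) * s
    if params.noise_sd > 0:
        conc = conc + rng.normal(0.0, params.noise_sd, z.size)
    conc = np.clip(conc, 0.0, None)
    return Profile(
        station=params.station, analyte=params.analyte, depths_m=z, values=conc
    )


def gen_incubation(params: IncubationSimParams) -> list[IncubationSeries]:
    """Generate replicate 15N incubation series with recorded true rates.

    Excess-N2 accumulation is linear in time with the isotope-pairing
    slopes b30 = D*F^2 and b29 = A*F + 2F(1-F)*D (per day; timepoints are
    hours), plus homoscedastic Gaussian noise on every timepoint.
    """
    rng = np.random.default_rng(params.seed)
    t_h = np.asarray(params.timepoints)
    t_d = t_h / HOURS_PER_DAY
    F = params.labeled_fraction
    D, A = params.true_denitrification, params.true_anammox
    b30 = D * F**2
    b29 = A * F + 2.0 * F * (1.0 - F) * D
    out = []
    for rep in range(params.n_replicates):
        e30 = b30 * t_d
        e29 = b29 * t_d
        if params.noise_sd > 0:
            e30 = e30 + rng.normal(0.0, params.noise_sd, t_d.size)
            e29 = e29 + rng.normal(0.0, params.noise_sd, t_d.size)
        out.append(
            IncubationSeries(
                experiment=params.experiment,
                station=params.station,
                depth_m=params.depth_m,
                timepoints_h=t_h.copy(),
                labeled_fraction_F=F,
                replicate=rep,
                excess_29N2=e29,
                excess_30N2=e30,
                true_denitrification=D,
                true_anammox=A,
            )
        )
    return out


def gen_c_series(
    true_rate: float,
    label_fraction_F: float,
    timepoints_h=PAPER_TIMEPOINTS_H,
    noise_sd: float = 0.0,
    station: str = "SYN",
    depth_m: float = 30.0,
    seed: int = 0,
) -> IncubationSeries:
    """Synthetic 13C-bicarbonate series: excess 13C-POC = rate * F * t."""
    if true_rate < 0:
        raise ValueError("true_rate must be >= 0")
    if not (0.0 < label_fraction_F <= 1.0):
        raise ValueError("label_fraction_F must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    t_h = np.asarray(timepoints_h, dtype=float)
    excess = true_rate * label_fraction_F * (t_h / HOURS_PER_DAY)
    if noise_sd > 0:
        excess = excess + rng.normal(0.0, noise_sd, t_h.size)
    return IncubationSeries(
        experiment="bicarbonate_13C",
        station=station,
        depth_m=depth_m,
        timepoints_h=t_h,
        labeled_fraction_F=label_fraction_F,
        excess_13C_POC=excess,
        true_c_fixation=true_rate,
    )
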