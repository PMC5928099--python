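"""Water-column flux, stoichiometry and upscaling bookkeeping.

Couples depth profiles of nitrate, sulfide and elemental sulfur across a
chemocline to the nitrate demand of chemolithoautotrophic sulfur oxidation,
via the flux-gradient method (flux = -Kz * dC/dz) and the denitrification
stoichiometry

    Eq. A:  5 H2S + 2 NO3- + 2 H+  -> 5 S0   + 1 N2 + 6 H2O   (partial)
    Eq. B:  5 S0  + 6 NO3- + 2 H2O -> 5 SO4= + 3 N2 + 4 H+    (S0 step)
    Eq. C:  5 H2S + 8 NO3-         -> 5 SO4= + 4 N2 + 4 H2O + 2 H+

with Eq. C = Eq. A + Eq. B (full oxidation to sulfate, 8/5 mol NO3- per
mol H2S).  The module also converts single-cell carbon-fixation rates into
population rates (volumetric, depth-integrated, percent of bulk dark CO2
fixation), maps carbon fixation onto denitrification / sulfur-oxidation
rate intervals through literature biomass yields, fits the cell-density vs
denitrification power law, and integrates shelf sulfur inventories.

Sign convention, fixed package-wide: depth is positive downward, so a
negative flux is upward.  Concentration units µmol/L are identical to
mmol/m^3, which keeps flux units in mmol m^-2 d^-1 without conversion
factors beyond seconds -> days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_KZ_M2_S",
    "SECONDS_PER_DAY",
    "Profile",
    "FluxEstimate",
    "Reaction",
    "StoichiometryModel",
    "YieldModel",
    "RegressionResult",
    "fit_gradient",
    "diffusive_flux",
    "estimate_flux",
    "nitrate_demand",
    "percent_attribution",
    "yield_convert",
    "volumetric_rate",
    "depth_integrate",
    "percent_contribution",
    "dn_regression",
    "inventory",
]

#: Eddy diffusivity for the mid-to-upper Peru shelf (m^2 s^-1), from
#: microstructure profiling; used as a stated constant, not derived here.
DEFAULT_KZ_M2_S = 1.4e-4

SECONDS_PER_DAY = 86400.0

# Atoms of S and N per formula unit, for reaction balancing checks.
_S_ATOMS = {"H2S": 1, "S0": 1, "SO4": 1, "S2O3": 2}
_N_ATOMS = {"NO3": 1, "NO2": 1, "NH4": 1, "N2": 2}


@dataclass
class Profile:
    """A depth-indexed series of one analyte at one station.

    Depths in metres, positive downward and strictly increasing.  Values
    are µmol/L for chemistry, cells/L for counts, nmol L^-1 d^-1 for
    volumetric rates (see ``unit``).
    """

    station: str
    analyte: str
    depths_m: np.ndarray
    values: np.ndarray
    unit: str = "umol/L"

    def __post_init__(self) -> None:
        self.depths_m = np.asarray(self.depths_m, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths_m.shape != self.values.shape:
            raise ValueError("depths_m and values must have equal length")
        if np.any(np.diff(self.depths_m) <= 0):
            raise ValueError("depths_m must be strictly increasing")


@dataclass(frozen=True)
class FluxEstimate:
    """A flux-gradient estimate over one depth window.

    ``flux`` is positive downward; a negative value indicates an upward
    water-column flux.
    """

    analyte: str
    z_top_m: float
    z_bottom_m: float
    gradient_mmol_m4: float  #: mmol m^-3 per m
    kz_m2_s: float
    flux_mmol_m2_d: float


class Reaction:
    """A balanced reaction as reactant/product coefficient maps."""

    def __init__(self, reactants: Mapping[str, float], products: Mapping[str, float]):
        self.reactants = dict(reactants)
        self.products = dict(products)

    def atom_balance(self, atoms: Mapping[str, int]) -> float:
        left = sum(c * atoms.get(sp, 0) for sp, c in self.reactants.items())
        right = sum(c * atoms.get(sp, 0) for sp, c in self.products.items())
        return left - right

    def __add__(self, other: "Reaction") -> "Reaction":
        net: dict[str, float] = {}
        for side, sign in ((self.reactants, 1), (self.products, -1),
                           (other.reactants, 1), (other.products, -1)):
            for sp, c in side.items():
                net[sp] = net.get(sp, 0.0) + sign * c
        reactants = {sp: c for sp, c in net.items() if c > 0}
        products = {sp: -c for sp, c in net.items() if c < 0}
        return Reaction(reactants, products)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Reaction):
            return NotImplemented
        return self.reactants == other.reactants and self.products == other.products

    def __repr__(self) -> str:
        fmt = lambda d: " + ".join(f"{c:g} {sp}" for sp, c in sorted(d.items()))
        return f"Reaction({fmt(self.reactants)} -> {fmt(self.products)})"


SULFIDE_TO_S0 = Reaction(
    {"H2S": 5, "NO3": 2, "H+": 2}, {"S0": 5, "N2": 1, "H2O": 6}
)
S0_TO_SULFATE = Reaction(
    {"S0": 5, "NO3": 6, "H2O": 2}, {"SO4": 5, "N2": 3, "H+": 4}
)
SULFIDE_TO_SULFATE = Reaction(
    {"H2S": 5, "NO3": 8}, {"SO4": 5, "N2": 4, "H2O": 4, "H+": 2}
)


@dataclass(frozen=True)
class StoichiometryModel:
    """Molar bookkeeping of nitrate-dependent sulfide/sulfur oxidation.

    Validates on construction that the partial (sulfide -> S0) and S0
    (S0 -> sulfate) steps sum to the full reaction and that S and N atoms
    balance in each.
    """

    partial: Reaction = field(default_factory=lambda: SULFIDE_TO_S0)
    s0_step: Reaction = field(default_factory=lambda: S0_TO_SULFATE)
    full: Reaction = field(default_factory=lambda: SULFIDE_TO_SULFATE)

    def __post_init__(self) -> None:
        for name, rxn in [
            ("partial", self.partial),
            ("s0_step", self.s0_step),
            ("full", self.full),
        ]:
            for label, atoms in [("S", _S_ATOMS), ("N", _N_ATOMS)]:
                imbalance = rxn.atom_balance(atoms)
                if imbalance != 0:
                    raise ValueError(f"{name} reaction does not balance {label}")
        if self.partial + self.s0_step != self.full:
            raise ValueError("partial + s0_step must equal the full reaction")

    @property
    def no3_per_h2s(self) -> float:
        """mol NO3- consumed per mol H2S fully oxidized to sulfate (8/5)."""
        return self.full.reactants["NO3"] / self.full.reactants["H2S"]

    @property
    def no3_per_h2s_partial(self) -> float:
        """mol NO3- per mol H2S oxidized only to S0 (2/5)."""
        return self.partial.reactants["NO3"] / self.partial.reactants["H2S"]

    @property
    def no3_per_s0(self) -> float:
        """mol NO3- per mol S0 oxidized to sulfate (6/5)."""
        return self.s0_step.reactants["NO3"] / self.s0_step.reactants["S0"]


@dataclass(frozen=True)
class YieldModel:
    """Biomass yields linking CO2 fixation to sulfur/nitrogen turnover.

    ``y_h2s_lo``/``y_h2s_hi`` bracket literature yields of aerobic sulfide
    oxidizers (mol CO2 fixed per mol H2S oxidized, default 0.35-0.58); the
    nitrate-based yields scale by the 5/8 H2S:NO3- ratio of the full
    denitrification stoichiometry.
    """

    y_h2s_lo: float = 0.35
    y_h2s_hi: float = 0.58
    stoichiometry: StoichiometryModel = field(default_factory=StoichiometryModel)

    def __post_init__(self) -> None:
        if not (0 < self.y_h2s_lo <= self.y_h2s_hi):
            raise ValueError("require 0 < y_h2s_lo <= y_h2s_hi")

    @property
    def y_no3_lo(self) -> float:
        return self.y_h2s_lo / self.stoichiometry.no3_per_h2s

    @property
    def y_no3_hi(self) -> float:
        return self.y_h2s_hi / self.stoichiometry.no3_per_h2s


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int


def fit_gradient(profile: Profile, z_top: float, z_bottom: float) -> float:
    """Concentration gradient (mmol m^-3 per m) over a depth window.

    Ordinary least-squares slope of concentration against depth for the
    samples falling inside [z_top, z_bottom]; a two-point window reduces to
    the finite difference.
    """
    if z_top >= z_bottom:
        raise ValueError("z_top must be < z_bottom")
    mask = (profile.depths_m >= z_top) & (profile.depths_m <= z_bottom)
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 samples inside [{z_top}, {z_bottom}] m "
            f"(found {int(mask.sum())})"
        )
    z = profile.depths_m[mask]
    c = profile.values[mask]
    slope, _ = np.polyfit(z, c, 1)
    return float(slope)


def diffusive_flux(gradient_mmol_m4: float, kz_m2_s: float = DEFAULT_KZ_M2_S) -> float:
    """Turbulent flux (mmol m^-2 d^-1) from a vertical gradient.

    flux = -Kz * dC/dz with Kz converted to m^2/day.  Positive downward;
    an analyte increasing with depth therefore yields a negative (upward)
    flux.
    """
    if kz_m2_s <= 0:
        raise ValueError("kz_m2_s must be > 0")
    return -kz_m2_s * SECONDS_PER_DAY * gradient_mmol_m4


def estimate_flux(
    profile: Profile,
    z_top: float,
    z_bottom: float,
    kz_m2_s: float = DEFAULT_KZ_M2_S,
) -> FluxEstimate:
    """Flux-gradient estimate for one analyte over one depth window."""
    grad = fit_gradient(profile, z_top, z_bottom)
    return FluxEstimate(
        analyte=profile.analyte,
        z_top_m=z_top,
        z_bottom_m=z_bottom,
        gradient_mmol_m4=grad,
        kz_m2_s=kz_m2_s,
        flux_mmol_m2_d=diffusive_flux(grad, kz_m2_s),
    )


def nitrate_demand(
    sulfide_flux: float,
    s0_flux: float = 0.0,
    model: StoichiometryModel | None = None,
    mode: str = "full_to_sulfate",
) -> float:
    """Nitrate demand (mmol m^-2 d^-1) of oxidizing the supplied S fluxes.

    Demand is magnitude arithmetic: flux signs are stripped (direction is
    logged) because the stoichiometry consumes moles of S regardless of
    transport direction.  ``full_to_sulfate`` oxidizes sulfide completely
    (8/5 NO3- per H2S) plus any S0 flux at 6/5; ``partial_to_S0`` stops at
    elemental sulfur (2/5 per H2S).
    """
    model = model or StoichiometryModel()
    if sulfide_flux < 0 or s0_flux < 0:
        logger.info(
            "nitrate_demand: using flux magnitudes (H2S %.3g, S0 %.3g)",
            sulfide_flux,
            s0_flux,
        )
    h2s = abs(sulfide_flux)
    s0 = abs(s0_flux)
    if mode == "full_to_sulfate":
        return h2s * model.no3_per_h2s + s0 * model.no3_per_s0
    if mode == "partial_to_S0":
        return h2s * model.no3_per_h2s_partial
    raise ValueError(
        f"unknown mode {mode!r}; use 'full_to_sulfate' or 'partial_to_S0'"
    )


def percent_attribution(demand: float, nitrate_flux: float) -> float:
    """Percent of the downward nitrate flux consumed by a demand, capped at 100."""
    if nitrate_flux <= 0:
        raise ValueError("nitrate_flux must be > 0 (downward supply)")
    if demand < 0:
        raise ValueError("demand must be >= 0")
    return min(100.0, 100.0 * demand / nitrate_flux)


def yield_convert(
    cfix: float,
    yields: YieldModel | None = None,
    process: str = "denitrification",
) -> tuple[float, float]:
    """Map a carbon-fixation rate onto a process-rate interval via yields.

    For ``process="denitrification"`` the interval is
    [cfix / y_no3_hi, cfix / y_no3_lo] in nmol N L^-1 d^-1; for
    ``"s0_oxidation"`` the per-S yields apply, giving nmol S L^-1 d^-1.
    """
    if cfix < 0:
        raise ValueError("cfix must be >= 0")
    yields = yields or YieldModel()
    if process == "denitrification":
        lo_y, hi_y = yields.y_no3_lo, yields.y_no3_hi
    elif process == "s0_oxidation":
        lo_y, hi_y = yields.y_h2s_lo, yields.y_h2s_hi
    else:
        raise ValueError(
            f"unknown process {process!r}; use 'denitrification' or 's0_oxidation'"
        )
    return cfix / hi_y, cfix / lo_y


def volumetric_rate(per_cell_rate_fmol_d: float, density_cells_l: float) -> float:
    """Population rate (nmol C L^-1 d^-1) = per-cell rate x cell density.

    fmol -> nmol carries the 1e-6 factor.
    """
    if per_cell_rate_fmol_d < 0 or density_cells_l < 0:
        raise ValueError("per-cell rate and density must be >= 0")
    return per_cell_rate_fmol_d * density_cells_l * 1e-6


def depth_integrate(profile: Profile, z_top: float, z_bottom: float) -> float:
    """Depth-integrated rate (mmol m^-2 d^-1) over [z_top, z_bottom].

    Trapezoidal rule on a volumetric-rate profile in nmol L^-1 d^-1
    (= µmol m^-3 d^-1); window endpoints are obtained by linear
    interpolation, and must lie inside the sampled depth range.
    """
    if z_top > z_bottom:
        raise ValueError("z_top must be <= z_bottom")
    z, v = profile.depths_m, profile.values
    if z_top < z[0] or z_bottom > z[-1]:
        raise ValueError(
            f"window [{z_top}, {z_bottom}] m outside sampled range "
            f"[{z[0]}, {z[-1]}] m"
        )
    if z_top == z_bottom:
        return 0.0
    inside = (z > z_top) & (z < z_bottom)
    zz = np.concatenate(([z_top], z[inside], [z_bottom]))
    vv = np.concatenate(
        ([np.interp(z_top, z, v)], v[inside], [np.interp(z_bottom, z, v)])
    )
    # nmol/L/d == umol/m^3/d; x m -> umol/m^2/d; /1000 -> mmol/m^2/d
    return float(np.trapezoid(vv, zz) * 1e-3)


def percent_contribution(
    group_integrated: float, bulk_integrated: float, digits: int | None = 0
) -> float:
    """Percent of bulk dark CO2 fixation attributable to one population.

    Capped at 100 (single-population rates can exceed the bulk estimate
    because of filter-size differences); rounded to ``digits`` decimals
    for report tables (``None`` disables rounding).
    """
    if bulk_integrated <= 0:
        raise ValueError("bulk_integrated must be > 0")
    if group_integrated < 0:
        raise ValueError("group_integrated must be >= 0")
    pct = min(100.0, 100.0 * group_integrated / bulk_integrated)
    return pct if digits is None else round(pct, digits)


def dn_regression(densities_cells_l, dn_rates) -> RegressionResult:
    """Power-law fit of denitrification rate against cell density.

    Ordinary least squares of log10(rate) on log10(density); non-positive
    pairs are excluded (their count is reported), and at least three valid
    pairs are required.
    """
    d = np.asarray(densities_cells_l, dtype=float)
    r = np.asarray(dn_rates, dtype=float)
    if d.shape != r.shape:
        raise ValueError("densities and rates must have equal length")
    ok = (d > 0) & (r > 0) & np.isfinite(d) & np.isfinite(r)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need >= 3 positive paired observations")
    res = stats.linregress(np.log10(d[ok]), np.log10(r[ok]))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_used=int(ok.sum()),
        n_excluded=n_excluded,
    )


def inventory(
    profiles: Mapping[str, Profile], station_areas_m2: Mapping[str, float]
) -> float:
    """Shelf inventory (moles) of one analyte from station profiles.

    Box estimator: sum over stations of area x depth-integrated
    concentration (µmol/L == mmol/m^3, integrated over the full sampled
    depth range of each profile).  Every station must carry an area weight.
    """
    total_mol = 0.0
    for station, prof in profiles.items():
        if station not in station_areas_m2:
            raise ValueError(f"missing area weight for station {station!r}")
        col_mmol_m2 = float(np.trapezoid(prof.values, prof.depths_m))
        total_mol += station_areas_m2[station] * col_mmol_m2 * 1e-3
    return total_mol
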