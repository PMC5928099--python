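# Methods

This note documents the models implemented in `omzflux`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical conventions that a
user extending the package should know.

## Single-cell rate model

A cell is treated as a rounded rod (cylinder with hemispherical caps) of
length *A* and diameter *B* in µm. Two biovolume variants are provided:

- `printed` (default): `V = πB²(0.125A − 0.0833B)`. This is the published
  coefficient pair. Note that it does **not** satisfy the sphere limit: at
  A = B it yields half the volume of a sphere of diameter B. The exact
  capsule formula has 0.25, not 0.125, as the leading coefficient.
- `geometric`: `V = πB²(0.25A − 0.0833B)`, the exact capsule, which reduces
  to πd³/6 at A = B.

The default reproduces the published calculation chain; the geometric
variant is available for users who prefer internal consistency. Both are
tested. This discrepancy is surfaced here deliberately rather than silently
resolved.

Carbon content follows the allometric law `fg C = 135 V^0.438`, chosen for
its conservative treatment of small cells (carbon density fg/µm³ decreases
with volume). fg↔fmol conversion uses an atomic mass of 12.011 g/mol
(configurable). A related bookkeeping note: a published cell-volume range
of 0.18–0.39 µm³ was reported as 61–83 fg C, whereas direct evaluation of
the law at those endpoint volumes gives 63.7–89.4 fg; the difference
presumably reflects per-cell averaging order or unrounded inputs. The
package always evaluates the law per cell.

Carbon turnover uses the linear ratio form
`f = (R_cell − R_bg)/R_DIC/t`, valid at low enrichment, with
R_bg = 0.0112 (natural 13C/12C abundance; configurable — the source
calculation chain does not print its value) and R_DIC derived from the
spike recipe by `label_fraction()`: 1 g of 13C-bicarbonate (≈85 g/mol) in
50 mL stock, 4.5 mL into a 4.5 L bottle over 2.2 mM ambient DIC gives
0.235 mmol 13C L⁻¹, an excess label fraction of 9.7%, and R_DIC ≈ 0.119.
An atom-fraction mode (`mode="atom_fraction"`) is provided and documented
but off by default; it converts ratios r to atom fractions r/(1+r) and
normalizes by the excess atom fraction of the DIC pool. The two modes
differ by a factor ≈ R_DIC/(R_DIC − R_bg) at low enrichment; the default
reproduces the published chain.

Negative turnovers (cell ratio below background) are returned as computed
and flagged, never truncated, so that simulation-based bias checks on
population means remain unbiased. Counting QC passes a cell iff
√N/N < 0.05 strictly on the minor-isotope count (N = 0 always fails); the
pass-set is monotone in the threshold.

Station means can be aggregated two ways: the mean of per-cell rates, or
mean turnover × mean carbon content. The published per-station means are
mutually consistent under the product form, so `station_summary` reports
both (`rate_percell_mean`, `rate_product`). Between-station contrasts use
one-way fixed-effects ANOVA.

## Incubation rate model

Excess 29N2 and 30N2 accumulate linearly over the 0/6/12/24/48 h design.
Time is converted to days internally so rates are nmol L⁻¹ d⁻¹. The
isotope-pairing inversion (D = b30/F², A = (b29 − 2((1−F)/F)b30)/F) is the
standard two-slope algebra for random-pairing denitrification plus
one-to-one anammox pairing; the primary description cites rather than
restates it, and this reading is adopted here. Standard errors propagate
linearly (slopes are independent OLS fits per channel); significance is a
two-sided t test with df = n_timepoints − 2; the detection limit is
median(SE) × two-sided t critical value at p = 0.05 with the same df
(sidedness is not stated in the source; two-sided is the conservative
choice). Campaign-specific printed detection limits require the cruise
regression set and are not reproduced; the procedure is validated on
synthetic campaigns instead (null series flagged ≤ α of the time, rates at
3× the computed limit detected >90% of the time).

Bulk dark CO2 fixation divides excess 13C-POC by label fraction × time,
either at the single 24-h endpoint (the bottle design) or by regression
over a series. The 15NO3− → NO2− production channel is handled by the
generic `labeled_product_rate` (slope/F), since the source implies but
does not detail its regression machinery.

## Flux and budget model

Depth is positive downward package-wide; `flux = −Kz · dC/dz`, so a
negative flux is upward. µmol/L ≡ mmol/m³ keeps flux units at
mmol m⁻² d⁻¹ with only the seconds→days factor on Kz (stated constant
1.4 × 10⁻⁴ m² s⁻¹ from microstructure profiling; no turbulence processing
here). Gradients are OLS slopes over a stated depth window (the source
does not say finite-difference vs regression; OLS degrades gracefully to
the finite difference on two-point windows). The default windows are
nitrate 12–30 m, sulfide 30–40 m, elemental sulfur 20–30 m.

The stoichiometry object validates on construction that sulfide→S0 and
S0→sulfate sum to the full sulfide→sulfate reaction and that S and N atoms
balance. Nitrate demand is magnitude arithmetic (flux signs are stripped
and logged): moles of S require moles of NO3− regardless of transport
direction. Note the source prints the downward nitrate flux with units
"mmol S m⁻² d⁻¹" — treated here as a typographical slip for mmol (N)
m⁻² d⁻¹. With the printed fluxes, demand/supply = 12.16/17 = 71.5%, which
the source rounds to "up to 70%"; the package reports the unrounded
percentage, capped at 100.

Upscaling multiplies per-cell rates by cell densities (fmol→nmol = 1e−6),
integrates volumetric-rate profiles by the trapezoid rule with linear
interpolation at window edges (exact on the piecewise-linear profiles
reported), and caps percent contributions at 100 (bulk rates from GF/F
filters can underestimate relative to 0.2 µm filters, so >100% occurs).
The cell-density–denitrification regression is OLS of log10(rate) on
log10(density) — the log base is unstated in the source; base 10 is used
as the printed functional form implies. Shelf inventories use a box
estimator (Σ area × depth-integrated concentration); the source's spatial
interpolation is not described, so nothing fancier is attempted.

## Synthetic data

The generators define the test conditions. Defaults: cells at 0.19 fmol C
cell⁻¹ d⁻¹ mean rate (shelf value), rate CV 0.3 and size CV 0.2 (typical
biological spread; sizes are published only as mean ± sd, so lognormal is
chosen to guarantee positivity), rod means 1.4 × 0.7 µm (mean biovolume
≈0.18 µm³, the shelf station mean), 24-h incubation, recipe-derived
R_DIC, 10⁴ expected minor-isotope counts (1% relative Poisson error, the
scale at which QC is comfortably passed). Counting noise acts on the
minor count only, with the major count exact — the 13C count dominates
ratio uncertainty. Profiles are logistic in depth (the source shows but
does not parameterize profile shapes) with 0.5 µmol/L Gaussian noise
truncated at zero; a `linear` shape provides the infinite-width degenerate
case whose gradient is exactly recoverable. Incubations use the 0/6/12/24/
48-h design with homoscedastic Gaussian noise (0.5 nmol N L⁻¹) — the
simplest model consistent with OLS slope estimation; replicate counts are
exposed as a parameter since the source does not state them per
experiment.

Not emulated: instrument physics (sputtering, drift, matrix effects), ion
images and ROI drawing, hybridization efficiency, bottle effects and
trace-O2 artefacts, and real covariance between cell size and activity.
Passing parameter-recovery tests therefore demonstrates correctness of
the estimators under the stated statistical model, not robustness to
instrument systematics.

## Numerical conventions and degenerate inputs

- Noise-free regression fits have SE = 0; the t test then resolves to
  p = 1 for a zero slope and p = 0 otherwise (flagged degenerate), so
  exact round-trip tests behave sensibly.
- Identical ANOVA groups (zero between-group variance) report F = 0,
  p = 1 rather than NaN.
- Two-point gradient windows reduce to finite differences; fewer than two
  points in a window, fewer than three timepoints in a regression, and
  empty SE lists are hard errors.
- Width draws exceeding the length draw are clipped to the length (rod
  invariant), which slightly skews the width distribution at high size
  CV; at the default CV the effect is negligible.
- Percent quantities are capped at 100 and rounded to integer for report
  tables (configurable).

## Problem sizes

The test suite calibrates estimators at sizes chosen to keep the full run
within seconds while leaving Monte-Carlo error far below the asserted
tolerances: 500 cells × 100 seeds for population-mean recovery, 1000 null
simulations for type-I error of the slope test (nominal 5%, asserted
within [3%, 7%]), 300 simulated campaigns for detection-limit behaviour,
and 100–200 seeds for bias and gradient-recovery checks.

## Known limitations

- The printed biovolume coefficients are reproduced as-is (see above);
  users comparing against capsule-geometry literature should use the
  `geometric` variant.
- Yield-based denitrification/S-oxidation intervals are transparent
  interval algebra on the yield bracket; published attributed-rate ranges
  mix unrounded inputs and are not exactly recoverable from any single
  pairing of printed endpoints, so no attempt is made to force them.
- The box inventory estimator ignores spatial covariance between stations.
- The flux-gradient method assumes steady state and a single constant Kz.
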