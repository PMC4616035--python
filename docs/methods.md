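# Methods

## Gas exchange model

The areal air–water CO₂ flux is

F = k · α · (pCO₂,water − pCO₂,air),

with k the gas transfer velocity (m d⁻¹), α the CO₂ solubility coefficient
(mol L⁻¹ atm⁻¹) and the gradient in µatm. A positive F is evasion to the
atmosphere. Because 1 mol L⁻¹ atm⁻¹ equals 1 mmol m⁻³ µatm⁻¹, the product
is already in mmol m⁻² d⁻¹ without an explicit conversion factor. pCO₂
reported in ppm is treated as µatm assuming 1 atm total pressure; the
difference is below the ±2% precision of field equilibrator/IRGA
measurements. No Schmidt-number conversion is applied to k: at the fixed
25 °C used for upscaling, Sc(CO₂) ≈ 600, so k₆₀₀ and k_CO₂ coincide and
the k column of the upscaling table is used as-is.

α(T, S) follows the standard Weiss-form polynomial
ln α = A₁ + A₂(100/T) + A₃ ln(T/100) + S·(B₁ + B₂(T/100) + B₃(T/100)²)
with T in kelvin; it is strictly decreasing in temperature
(α ≈ 0.0340 mol L⁻¹ atm⁻¹ at 25 °C, 0.0776 at 0 °C, freshwater). The CH₄
Bunsen solubility uses the same functional form with the freshwater CH₄
coefficients, divided by 22.414 L mol⁻¹ to obtain a molar Henry constant
(≈1.41×10⁻³ mol L⁻¹ atm⁻¹ at 25 °C).

### Headspace back-calculation

Dissolved CH₄ is measured by equilibrating a water sample under an N₂
headspace in a sealed serum vial (default geometry: 50 mL vial, 20 mL
headspace over 30 mL water) and measuring the equilibrium headspace mixing
ratio x by GC. The original concentration follows from a two-phase mass
balance: gas-phase moles x·P·V_g/(R·T) (ideal gas) plus dissolved moles
x·P·β(T)·V_w (Henry's law), divided by V_w. The result is exactly linear
in x, and the forward and inverse balances round-trip to 10⁻¹⁰ relative
precision. The equilibration temperature and laboratory pressure are
explicit inputs (defaults 25 °C, 1 atm) since they are properties of the
laboratory, not of the field protocol.

## Stratification and statistics

Records carry river, date, coordinates, channel class, pCO₂ (ppm) and CH₄
(nmol L⁻¹). Channel classes are mainstem (MS), tributaries wider than
100 m (T>100m) and narrower (T<100m); a width of exactly 100 m is assigned
to the large class so the partition is total. Validation rejects and
counts rows with non-positive concentrations (a positive CH₄ is required
for the log transform), unknown classes or unparseable numerics; no other
outlier screening is applied.

Summaries use order statistics with type-7 (linear interpolation)
percentiles: median, mean, quartiles and 5–95 percentile whiskers, plus
min/max. Basin-wide ranges pool all classes of a river. Between-class
effects within a river use the tie-corrected Kruskal–Wallis test;
pairwise river comparisons use the two-sided Mann–Whitney U test, exact
for small tie-free samples. All pairwise p-values are reported rather
than a selected subset; the working significance level is 0.05. CH₄–pCO₂
coupling per stratum is an OLS of log₁₀(CH₄) on untransformed pCO₂,
pooling all cruises.

## Wetland regression

For each channel class, the per-basin median pCO₂ is regressed on the
basin's wetland fraction (fraction of catchment with continuous, seasonal
or periodic standing water or saturated soils) by unweighted OLS — basins
contribute equally regardless of their sample size, since the basins span
roughly n = 9 to n = 442 and weighting by n would let one or two
data-dense basins dictate the line. At least three basins with distinct
fractions are required. The fitted slope, intercept, their standard
errors and the full 2×2 coefficient covariance are retained; models
export to JSON and reload bit-exactly. Predictions are affine in the
fraction and clamped below at 0 ppm: negative partial pressures are
unphysical, but sub-atmospheric predictions are kept because they
legitimately produce invasion (negative) fluxes.

## Upscaling

The upscaling table has one row per COSCAT catchment unit with a
representative latitude, a wetland fraction, and k and water surface area
for two channel size classes (streams <100 m, rivers ≥100 m). Because
areas are structured by stream order, mainstem cannot be separated from
large tributaries; the MS and T>100m regression predictions are therefore
averaged and applied to the large size class, while the T<100m line
drives the small class. Fluxes use a constant 25 °C solubility and
390 ppm atmospheric pCO₂ (both configurable, enabling sensitivity runs),
are scaled by the class areas (mmol m⁻² d⁻¹ × km² → PgC yr⁻¹ with
365.25 d yr⁻¹ and 12.011 g C mol⁻¹), and cells with latitude in the
inclusive band [−30°, 30°] are summed. The total is additive over any
partition of the cell set and bit-deterministic for identical inputs.

## Monte Carlo error propagation

Each of the default 1000 iterations redraws:

1. **Regression coefficients** — one (intercept, slope) pair per channel
   class from a bivariate normal with the fitted OLS covariance, shared
   by all cells within the iteration (the regression is one model, not
   per-cell noise). Independent sampling of slope and intercept is
   available as a flag; a non-positive-semi-definite covariance triggers
   an automatic, logged fallback to independent sampling.
2. **k and area factors** — multiplicative perturbations centred on 1
   with relative SDs 0.10 (k) and 0.31 (area), drawn from a normal
   truncated at zero. The "±" of the input uncertainties is interpreted
   as a 1-SD relative error; a uniform half-range interpretation is
   available via `dist="uniform"`. By default one k draw and one area
   draw per iteration shift every cell together
   (`error_correlation="global"`): the dominant GIS error sources (choice
   of hydraulic equation, k parameterization) are systematic, and the
   correlated treatment is also the conservative one (a larger ensemble
   SD than independent per-cell draws, which average out across cells).

The ensemble mean, SD and 2.5/50/97.5 percentiles are reported alongside
the deterministic total; both the ensemble mean and the deterministic
value are given because a point estimate quoted with an MC uncertainty
can refer to either. Everything is reproducible from a single integer
seed. When every perturbation is disabled the ensemble is degenerate and
the SD is reported as exactly zero (the naive ensemble SD of N identical
floats carries an ~10⁻¹⁷ residue from the mean computation, which is
suppressed).

In the small-uncertainty limit the ensemble relative SD matches
first-order propagation, √(σ_pCO₂-term² + σ_k² + σ_A²); because the total
is linear in area, an area-only relative SD passes through exactly (up to
the ~0.4% moment shift introduced by the zero-truncation at a relative SD
of 0.31).

## Synthetic data

The measurement generator draws per-stratum pCO₂ from a log-normal
(configured median and geometric SD — river-channel gas data are strongly
right-skewed, spanning one to four orders of magnitude within a basin)
and couples CH₄ through log₁₀CH₄ = a + b·pCO₂ + ε with Gaussian ε, which
makes the log-linear fit's ground truth exact. Coordinates and dates are
uniform in configured bounds. The `study_preset` encodes the study's
structure: 136 Amazon and 280 Congo paired records, class-ordered pCO₂
medians (MS < T>100m < T<100m) in both basins, a higher Amazon mainstem
pCO₂, CH₄ three to four times higher in the Congo in every class, a weak
negative CH₄–pCO₂ coupling in the Amazon mainstem and strong positive
coupling in small streams. The magnitudes (medians of 3 200–7 500 ppm and
geometric SDs of 1.5–1.7) are the package's own choice of realistic
lowland-tropical values.

The COSCAT generator draws latitudes uniformly across (and slightly
beyond) the tropics, wetland fractions from a Beta(1.5, 8) (bounded on
[0, 1], right-skewed, mean ≈ 0.16), and k and areas from log-normals
(medians 4 and 2.5 m d⁻¹; 300 and 700 km² per cell). It returns, next to
the table, the exact tropical total implied by the configured true
regression lines, computed with the generator's own arithmetic so that
recovery tests compare two independent code paths.

What the generators do **not** emulate: spatial autocorrelation along a
river network, seasonality of the flood pulse (dates are uniform, not
stage-dependent), measurement error on pCO₂/CH₄ beyond the log-normal
scatter, correlation between k and channel size within a cell, and any
mechanistic wetland CH₄ production. A passing end-to-end test therefore
demonstrates correctness of the estimators and the propagation machinery
under the stated distributional assumptions, not that those assumptions
hold for any particular field data-set.

## Problem sizes and numerical choices

Default test-suite problem sizes — 28–100 records per stratum, six basins,
40–60 COSCAT cells, 10³ Monte Carlo iterations (10⁵ for the
delta-method and pass-through checks, 50 replicate seeds for the coverage
check) — were chosen so the full chain, including parameter-recovery
statistics, runs in seconds while keeping Monte Carlo error well below the
tolerances being asserted.

Ties in rank tests use average ranks with the standard tie corrections; a
sample in which every value is identical across all groups returns H = 0,
p = 1 rather than an error. Percentiles are type 7 throughout. OLS is
solved via statsmodels' QR-based path; coefficient recovery tests assert
agreement with explicit normal-equation arithmetic to 10⁻¹⁰ relative.

## Limitations

- The upscaling consumes a COSCAT table; it does not reconstruct one from
  GIS sources, so results are only as good as the supplied k and area
  columns.
- Only three uncertainty sources are propagated; water temperature,
  atmospheric pCO₂ and the wetland fractions themselves are treated as
  exact.
- The wetland regression is a single-predictor straight line by design;
  it will extrapolate linearly (with a 0 ppm floor) outside the fitted
  wetland-fraction range.
- CH₄ is analysed and modelled at the concentration level only; no CH₄
  flux or ebullition estimate is produced.
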