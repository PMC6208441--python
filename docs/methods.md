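# Methods

This document records the model equations as implemented, the parameter
choices and their rationale, the numerical conventions, and the known limits
of the synthetic-data generators. The package is a desk-scale implementation
of a satellite-driven rice productivity pipeline: multi-angle reflectance →
BRDF-corrected NDVI → paddy classification → surface insolation → within-season
crop-model calibration → gridded yield/NPP maps. All inputs are synthetic; the
generators are part of the package and every stage can be exercised end to end
on one CPU in minutes.

## 1. BRDF inversion and BAR NDVI (`gramirice.brdf`)

Surface reflectance follows the Ross-Thick Li-Sparse-Reciprocal (RTLSR)
kernel model

    rho(theta_s, theta_v, phi) = f_iso + f_geo * k_geo + f_vol * k_vol

with the Ross-Thick volumetric kernel and the reciprocal Li-Sparse geometric
kernel at the standard crown shape (h/b = 2, b/r = 1); the arccos argument of
the crown overlap is clamped to [-1, 1] so grazing geometries stay finite.
Kernel weights are estimated per band by plain (unweighted) ordinary least
squares on the design [1, k_geo, k_vol] over a 16-day rolling window
[d − 8, d + 7] for every day d.

Quality flags: `full` needs ≥ 7 observations (MODIS heritage) and a physically
sane fit (f_iso ≥ 0); 3–6 observations or a negative f_iso give `fill`
(parameters copied from the nearest previous full window); < 3 observations or
a rank-deficient geometry give `failed` (NaN output, never an exception).

**BAR convention.** For a geostationary sensor the view direction is fixed and
the angular diversity comes from the diurnal sun sweep, so BRDF-adjusted
reflectance (BAR) is referenced to the fixed view geometry and the window-mean
sun — not normalised to nadir as in the polar-orbiter NBAR product. Two
details matter numerically:

1. *Evaluation at mean kernels, not kernels of mean angles.* During steep
   green-up or senescence the within-window reflectance trend leaks into the
   angular kernel weights (the OLS fit has no time regressor). Evaluating the
   fitted BRDF at the kernels *of* the mean angles does not cancel that
   leakage and biases NDVI by several 0.01. `rolling_bar_ndvi` instead
   averages the fitted BRDF over the window's actual sun positions, which for
   an OLS fit equals the window-mean fitted reflectance, cancelling the
   leakage exactly. The residual error is the curvature-of-phenology
   window-mean bias, ≲ 0.01 NDVI for logistic rates up to 0.12 d⁻¹.
   `bar_reflectance` remains the point-geometry evaluator.
2. *Fractional acquisition times.* The synthetic schedule records day + hour/24
   so the 16-day window is time-symmetric about its labelled day; integer-day
   timestamps give a half-day phase lag worth ~0.01 NDVI on steep limbs.

NDVI = (NIR − Red)/(NIR + Red), clipped to [−1, 1], NaN when the band sum is
non-positive.

## 2. Surface insolation (`gramirice.insolation`)

Clear-sky irradiance is a Bird-style broadband parameterisation with
Kasten–Young relative air mass m:

    S_I = S0 E0 cos z · tau_oz tau_w tau_r tau_a           (direct)
    S_R = S0 E0 cos z · tau_oz tau_w tau_a (1 − tau_r)/2   (Rayleigh diffuse)
    S_A = S0 E0 cos z · tau_oz tau_w tau_r (1 − tau_a)·0.84 (aerosol diffuse)

with S0 = 1361 W m⁻², Ångström aerosol transmittance
tau_a = exp(−m · aod_550 · (0.70/0.55)^−1.3), and zenith angles ≥ 90° treated
as night (all components zero). Cloudy scenes multiply the clear-sky total by
a cloud factor inferred from zenith-normalised visible reflectance
ρ′ = ρ/cos z: CF falls linearly from 1 at the clear reference (ρ′_clear,
default surface reflectance 0.15) to a floor of 0.05 at ρ′_max = 0.9. A scene
is cloudy when its reflectance exceeds the clear reference by more than 0.08
(or when an explicit cloud mask says so). Daily totals treat each hourly value
as the mean irradiance of its hour: sum(S_T) · 3600 · 10⁻⁶ MJ m⁻² d⁻¹ (ten
daylight hours at a constant 500 W m⁻² integrate to exactly 18.0 MJ m⁻² d⁻¹).

## 3. Paddy classification (`gramirice.classify`)

Per-pixel NDVI time series are reduced to phenology metrics: the series is
linearly interpolated to a daily grid, smoothed with a Savitzky–Golay filter
(window 15 d, order 2), and summarised by peak value/date, steepest green-up
and senescence rates and the senescence date, plus the paddy classification
index

    PCI = (NDVI_harvest − NDVI_transplant) / (NDVI_harvest + NDVI_transplant)

anchored at DOY 140/270 with a ±8-day tolerance (the BRDF window half-width).
PCI exploits the flooded-field signal: paddies are water at transplanting
(very low NDVI) and vegetated near harvest, so their PCI is strongly positive.

Terrain covariates come from the DEM: Horn 3×3 slope, and the topographic
wetness index TWI = ln(a / tan β) with D8 flow accumulation, specific
catchment area a = accumulated cells × cell size, and tan β floored at 0.001.

The classifier is a 1000-tree random forest. Feature ranking is recursive
feature elimination: each round refits a forest on the surviving features of
the full training data and drops the least important one; subset sizes along
the ranking are scored by repeated stratified 10-fold cross-validation (5
repeats, 200-tree forests for the CV inner loop — a compute choice, the
production forest stays at 1000 trees). The 20-seed ranking-stability assay in
the acceptance suite uses 300-tree forests per elimination round for the same
reason; spot checks at 1000 trees give identical rankings.

## 4. GRAMI-rice crop model (`gramirice.grami`)

Daily state update from transplanting:

- thermal time: dGDD = max(0, (Tmax+Tmin)/2 − T_base), dev = GDD/GDD_maturity;
- biomass: dM = RUE · f_PAR · S · (1 − exp(−k_ext · LAI)) with daily
  insolation S in MJ m⁻² d⁻¹;
- leaf allocation: a logistic share p = 1/(1 + exp(a(dev − b))) of dM becomes
  leaf area via the specific leaf area, dLAI⁺ = SLA · p · dM;
- senescence: dLAI⁻ = c · max(0, dev − D_sen) · LAI;
- maturity at dev ≥ 1; yield = HI · AGDM · 0.01 t ha⁻¹; NPP accumulates
  0.45 · dM (carbon fraction).

Crop constants (rice defaults, configurable): T_base 8 °C, GDD_maturity
1600 °C d, D_sen 0.6, k_ext 0.6, RUE 2.8 g MJ⁻¹, SLA 0.022 m² g⁻¹, HI 0.45,
PAR fraction 0.48. Under these constants the default parameter set describes
*potential* (unstressed, density-saturated) growth: peak LAI reaches ~35–40
and yield ~15.5 t ha⁻¹, well above field values. The VI–LAI link absorbs the
scale: log VI = log k + (2/3) log LAI (a surface-vs-volume exponent), with
intercepts chosen per index (NDVI 0.080, RDVI 0.055, OSAVI 0.065, MTVI 0.060)
so the default trajectory spans a plausible index range (peak NDVI ≈ 0.9). In
an operational setting the intercept is a per-site regression constant.

**Within-season calibration** is a MAP fit of θ = (L0, a, b, c):

    J(θ) = Σ ((VI_obs − VI_sim(θ))/σ_obs)² + Σ ((θ − μ)/σ_prior)²

with Gaussian priors μ = (0.1, 8, 0.45, 0.05), σ_prior = 50% of μ, and box
bounds [0.2 μ, 5 μ] (b capped at 1.49). Minimisation is L-BFGS-B from the
prior mean plus 8 seeded Latin-hypercube restarts; objective ties break toward
the prior mean so results are deterministic. σ_obs may be a vector —
gap-filled retrievals are down-weighted (σ doubled) in the grid pipeline — and
σ_obs = ∞ gives the prior-dominated limit. The exposed surface follows the
Model/Results pattern: `WithinSeasonModel(...).fit()` returns a
`WithinSeasonResults` with estimates, finite-difference-Hessian standard
errors, residual diagnostics, `summary()`, `simulate()` and `plot()`.

Because the estimator is MAP, noiseless data with σ_obs = 0.03 still shrinks
estimates ~3% toward the prior when the truth is off-mean; the noiseless
recovery check therefore declares σ_obs = 10⁻³ (an honest description of
noiseless observations), recovering parameters to < 1% relative error.

## 5. Grid pipeline (`gramirice.grid`, `gramirice.gridio`)

Each paddy-mask pixel is calibrated and simulated independently. Pixel
optimizer seeds derive from counter-based substreams
`default_rng([seed, 777, pixel_id])`, so grid results are bit-identical across
repeated invocations and invariant to processing order or chunking. Failed
pixels (insufficient observations, incomplete season, optimizer exceptions)
become nodata and a log count, never an abort. Rasters are ESRI ASCII grids
with a JSON sidecar for CRS/affine (a text substitute for GeoTIFF; rasterio is
deliberately not a dependency), observations are CSV.

## 6. Synthetic generators and their limits (`gramirice.synth`)

Every generator is a pure function of (config, seed) through
SeedSequence-style substreams, so pixels are independent and order-invariant.

- *Phenology*: amplitude-normalised double logistic (the annual maximum equals
  the configured peak exactly; the normalising maximum is taken over the full
  year so the curve is a fixed function of DOY). Paddy pixels add a
  transplanting flood dip (−0.10 ± 0.02, Gaussian width 10 d) — the water
  signal the PCI is built on. Non-paddy vegetation (upland crop, hillside
  grassland) shares the monsoon growing season with jittered dates/rates but
  an un-flooded spring base, so class information is carried by design in
  PCI and terrain rather than curve-shape descriptors.
- *Landscape*: DEM = smoothed Gaussian noise (σ = 6 cells, 200–600 m) plus a
  150 m regional tilt; paddy labels threshold a suitability score
  −1.4 z(elev) − 0.4 z(slope) + 1.0 z(TWI) + N(0, 0.2) at the quantile that
  realises the configured paddy fraction.
- *Observations*: diurnal geostationary schedule (hours 9–16, fixed view
  zenith 40°, lat 38.5°N, SZA < 85°, fractional timestamps), Bernoulli cloud
  gaps, optional contiguous 20-day monsoon block mid-season.
- *Weather*: sinusoidal temperature climate (annual mean 10 °C, amplitude
  13 °C) with Gaussian anomalies; daily insolation integrates the hourly
  clear-sky model and is damped by stochastic cloud whose frequency peaks in
  late July.

Known realism limits: reflectance fields are isotropic or single-BRDF per
pixel (no mixed pixels, no topographic-BRDF coupling); cloud gaps are
independent apart from the monsoon block (no spatial correlation); the
temperature and cloud climates are stationary sinusoids (no interannual
variability, cold spells, or typhoons); the flood dip is a fixed-shape
Gaussian rather than a hydrological water balance; and the crop truth in grid
scenes is homogeneous across pixels. These are deliberate: the generators
exist to verify estimator properties, not to emulate a specific sensor.

## 7. Problem sizes and budgets

Default sizes are the package's own choices, set so the full test suite runs
on one CPU in well under the time budgets: classification scene 50×50 pixels
(500 m cells), grid pipeline demonstrations 10×10 to 20×20, 365-day years,
50-seed Monte Carlo for yield error. Measured on one CPU: a single
within-season calibration ≈ 0.3–0.9 s (2–8 restarts), the 20×20 grid
(107 paddy pixels, 2 restarts) ≈ 50–80 s per run, the 20-seed RFE stability
assay ≈ 180 s, the 50-seed yield Monte Carlo ≈ 105 s.

## 8. Numerical conventions

- Angles are degrees at every public interface, radians internally; relative
  azimuth 0° is forward scattering.
- DOY is 1-based and may be fractional (acquisition time).
- Yields in t ha⁻¹ (= g m⁻² × 0.01), insolation W m⁻² hourly and
  MJ m⁻² d⁻¹ daily.
- Grids are row-major, row 0 = north; pixel_id = row · ncols + col.
- Nodata is NaN in memory and −9999 in ASCII rasters.
- All stochastic APIs take explicit integer seeds; nothing reads global RNG
  state.
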