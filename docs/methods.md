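# Methods

## Scope and model structure

The package projects *relative* shallow-water coral cover — cover divided
by its start-of-run value — at single sites characterized by a monthly SST
record. Three processes act on cover: temperature-dependent net growth,
a calcification penalty from declining aragonite saturation (Ω_a), and
episodic mortality from heat-stress (bleaching) years. Everything else
(recruitment/connectivity, taxonomic succession, light and turbidity,
local anthropogenic stressors, reef-scale carbonate chemistry) is out of
scope by design.

### Cover update

Cover is integrated on an annual step:

    C_{y+1} = C_y · (1 + τ·G(T̄_y)·A(Ω_y) − m₀) · (1 − M(DHM_y))

The update is multiplicative: growth and background mortality act as a
net annual rate, and a bleaching year culls a fraction of whatever cover
is present. This is the simplest form consistent with three constraints
the model imposes: equilibrium at the start year, abrupt vertical drops
in event years, and geometric recovery between events. Growth is applied
before the year's episodic cull; the opposite order is available
(`mortality_first`) and its effect is small because the within-year
growth increment is a few percent (tested).

* `τ` (`baseline_turnover`, default 0.05 yr⁻¹) sets the gross growth
  scale at equilibrium, i.e. the pace of recovery after mortality — a
  decadal-scale recovery horizon typical of reef monitoring estimates.
* `m₀` is not free: it is calibrated once, `m₀ = τ·G(T̄₀)·A(Ω₀)`, so that
  a stationary climate holds cover at exactly 1.0 (conservation verified
  to 1e−9 over 100 years in the tests). Because the Ω reference is the
  start-year Ω, `A(Ω₀) = 1` and the calibration reduces to `τ·G(T̄₀)`.
* The start-year driving temperature `T̄₀` should be the *climatological*
  annual mean of the reference record, not the first simulated year's
  mean; passing a noisy first-year mean leaves a small spurious
  disequilibrium.
* Cover is floored at 0 and not capped at 1: with bleaching disabled,
  cool-climatology sites legitimately gain cover as warming moves them
  toward their growth optimum.
* Trajectory values are start-of-year states: `cover[i]` reflects all
  updates through year `i − 1`, and `cover[start_year] = 1` exactly.

### Growth curve

The cubic G(T) is anchored entirely by the site climatology: unit peak at
`clim_max − 2·clim_sd`, zeros at `clim_min − 5 °C` and `clim_max + 5 °C`,
solved exactly as a 4×4 linear system (two roots, stationary peak, unit
peak value). `clim_sd` is the standard deviation of the 12 climatological
monthly means — the spread of the mean seasonal cycle — not the
interannual SD of the warmest month; the alternative reading is exposed
via `Climatology.monthly_sd`. The unit peak is a normalization choice:
the absolute growth scale lives in `τ`, keeping the curve "relative".

Beyond its zeros the cubic is evaluated as-is (net decline) down to a
floor of −1; a cubic eventually turns around far outside its calibrated
range, and the floor keeps extrapolation bounded rather than meaningful.
If the peak anchor falls outside the open interval between the zeros the
fit raises `InfeasibleCurveError` rather than producing a nonsense curve;
ensemble drivers log and exclude such members (the perturbation
instability mechanism — see sensitivity).

### Carbonate chemistry

Ω_a is computed from (temperature, pCO2, salinity, total alkalinity) by
solving total alkalinity for [H⁺] with bracketed root finding, using
standard constants (Weiss 1974 K0; Lueker et al. 2000 K1/K2, total scale;
Dickson 1990 KB; Millero 1995 KW; Mucci 1983 aragonite Ksp; Ca and total
boron proportional to salinity). Surface pCO2 (µatm) is taken numerically
equal to atmospheric CO2 (ppm) on an annual step — the annual
air–sea equilibration assumption. Lookups go through a rectangular
(T × pCO2) table with bilinear interpolation, exact at nodes, with no
silent extrapolation; interpolation error against the direct solve is
< 0.05 Ω units on the default grid (1 °C × 25 µatm).

Defaults are salinity 35 and total alkalinity 2400 µmol/kg. Alkalinity is
the one knob with real leverage on absolute Ω; 2400 µmol/kg sits at the
upper end of subtropical open-ocean surface values and yields the
present-day subtropical reference point Ω ≈ 3.8 at (25 °C, 370 µatm)
declining to ≈ 2.5 at 700 µatm, which is the calibration this model's
calcification penalty is defined against. Both are configurable.

The calcification multiplier is strictly linear per Ω unit:
`1 − s·(Ω_ref − Ω_t)` clipped to [0, 1], with no credit for Ω above the
reference. Note that at `s = 0.3` the 3.8 → 2.5 drop gives a 39 %
reduction; a "roughly 30 %" shorthand sometimes quoted for that drop is
not what the linear definition produces, and the definition is
implemented as stated rather than tuned to the shorthand.

### Episodic mortality

Annual DHM is the calendar-year sum of monthly exceedances above the
bleaching threshold (warmest climatological monthly mean + 1 °C): two
months at +2 °C give 4 DHM. Mortality in an event year is a quadratic in
DHM *through the origin*, fitted by least squares; the zero intercept
guarantees stress-free years kill nothing (a free-intercept variant
exists for fit diagnostics only). Evaluated mortality is clipped to
[0, 1]. Adaptation is a linear drift of the threshold (0–2 °C per
century) applied to episodic mortality only — the growth curve does not
adapt.

The packaged observation tables (`all_data`, `mhi_nwhi`, `carib`) are
synthetic: the bleaching-event (DHM, mortality) coordinates they emulate
are not tabulated in any packaged source, so the fixtures reproduce only
the qualitative structure (Caribbean 2005 steeper than the Hawaiian
events, positive curvature, non-decreasing fits) and are labelled
non-authoritative in their headers. Fits to them must not be compared
against any published coefficients.

## Downscaling

Model runs are screened against the historic record over their overlap:
bias = difference of means; seasonal difference = |SD(model residuals) −
SD(historic residuals)| / SD(historic residuals), where residuals are
about a 4th-order polynomial trend in centred fractional year (centring
keeps the normal equations conditioned over a century). Both limits
(3 °C, 1) are strict inequalities — a run exactly at the limit fails.

The transform itself: fit the 4th-order trend to the scenario series,
map its residuals through the normal CDF at the model residual moments
and invert with the historic residual SD (under normality this is the
affine map `(r − μ)·σ_hist/σ_model`; the CDF path is kept as the defined
operation), then subtract the 20th-century bias. The model's own slow
trend passes through untouched (century net trend preserved within 5 %,
tested), the overlap-period mean matches the historic record, and the
operation is idempotent within tolerance.

One pooled residual distribution per series is used for the CDF map;
per-calendar-month distributions appear only in the Monte Carlo route,
where they are stated per month. The Monte Carlo trend is built from
bias-corrected (not fully rescaled) model series: each is deseasonalized
with its own climatological monthly means, smoothed with a 25-month
centred moving average (edge reflection), and averaged across models.
The deseasonalize-then-smooth order is an implementation choice: a plain
moving average leaves seasonal-phase artefacts of a few tenths of a
degree at the series edges, exactly where the projection starts.
Simulated members are trend + historic seasonal cycle + independent
per-month normal draws; member `k` of seed `s` uses the dedicated stream
`(s, k)`, so members are individually reproducible and adding members
never perturbs earlier ones.

## Ensembles and probabilities

The individual-model ensemble runs one trajectory per surviving model
run; the Monte Carlo ensemble defaults to 500 members (end-state spread
is stable well below that: the tests check SD stability between 100 and
200 members at 15 %). Decline probabilities fit a normal distribution to
member cover values at the evaluation year (sample mean/SD, no robust
variant) and report the CDF below `1 − decline_frac`; a zero-variance
ensemble returns 0 or 1 by mean position. Evaluation years default to
2050 and 2099.

Case presets: `less_resilient` (no adaptation, s = 0.3),
`more_resilient` (1 °C/century adaptation, CO2 module off),
`no_bleaching` (both stressor modules off — pure growth dynamics, an
instructive rather than realistic configuration; defining it with the
CO2 module off also makes the resilience ordering a structural dominance:
since Ω multiplier ≤ 1 and episodic mortality ≥ 0 under shared forcing,
`no_bleaching ≥ more_resilient ≥ less_resilient` pointwise), and
`validation_20c` (less-resilient parameters on a 1900-start hindcast).

## Sensitivity protocol

One parameter varies across its level grid with everything else fixed,
including the SST realizations (common random numbers), so level-to-level
differences isolate the parameter. Default grids: adaptation
{0, 0.5, 1, 1.5, 2} °C/century; Ω coefficient {0, 0.15, 0.3, 0.45}; the
three mortality tables; five independent growth-curve anchor
perturbations (zeros ± 0.5 °C uniform, peak 0–2 °C warmward uniform).
The total run budget (`n_runs`, default 200 per parameter) is split
evenly across levels. The metric is normalized variance — population
variance divided by mean — of per-level ensemble means, and separately of
per-level member SDs, at 2050 and 2099. Members whose |cover − 1|
exceeds 5 (a 500 % change) are flagged unstable and the mean-variance is
reported both with and without them; instability arises when a perturbed
growth curve places the start-year temperature near a zero of the cubic,
making `m₀` tiny and the relative dynamics violent.

## What the synthetic generator does and does not emulate

Generated SST is climatological cycle + slow polynomial trend +
independent per-calendar-month Gaussian noise; model-style series add a
constant bias and a seasonal-amplitude factor applied to all sub-trend
variability. Site presets (JOH/OAH/FFS/MID) are illustrative fixtures
reproducing the latitudinal ordering (MID coldest, widest seasonal range
and noisiest; JOH warmest and quietest); they are not transcriptions of
any observational dataset. The generator deliberately omits interannual
autocorrelation (ENSO-like persistence), spatial structure, and
non-Gaussian tails; consequently, passing tests demonstrate correct
mechanics and parameter recovery, not realism of event clustering — real
bleaching years cluster more than independent draws do. The CO2 preset
is a symmetric logistic from 370 to 700 ppm over 2000–2099 (mid-range
emissions shape) with exact endpoints.

Default experiment sizes used in the test suite (three screened model
runs, 100-member Monte Carlo ensembles, 50-run sensitivity budgets) are
chosen to exercise every code path at desk scale; all of them are plain
function arguments and scale up unchanged.

## Numerical choices and degenerate inputs

* Polynomial fits use `numpy.polynomial` with centred abscissae.
* The carbonate solve brackets pH in [4, 10] with `brentq` (xtol 1e−12).
* A zero model-residual SD, a zero-spread climatology, or a zero-mean
  normalized-variance input raise typed errors rather than propagate NaN.
* Monthly series validate contiguity on construction and name the first
  offending (year, month) on gaps or duplicates; readers sort records, so
  on-disk ordering is irrelevant.
* NetCDF I/O uses xarray's scipy backend (classic NetCDF3, CF time axis,
  variable `tos`); CSV is the primary interchange format.

## Known limitations

* The cover update is an annual scalar balance; there is no within-year
  phenology, no recovery lag after events, and no cover ceiling.
* Adaptation is a deterministic linear threshold drift — a bounding
  device, not a mechanism.
* The Ω penalty treats calcification as the sole pathway and ignores
  community-level effects (crustose coralline algae, cementation,
  bioerosion).
* Sites are independent; there is no larval connectivity or shared
  regional variability between runs at different presets.
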