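# Methods

This note documents the models, the numerical choices, and what the
synthetic-data validation does and does not demonstrate.

## Chamber flux estimation

A closed, fan-mixed chamber is sealed over a vegetation plot and CO₂
(ppm ≡ µmol mol⁻¹) is logged at 1 Hz for 180 s; transparent closures
measure net ecosystem exchange (NEE), darkened closures ecosystem
respiration (ER). The first and last 10 s are discarded (sealing and
removal disturbance), leaving a 160-reading window.

The concentration is modelled as a linear drift plus an exponential
approach to chamber equilibrium:

    C(t) = Cm + a (t − tz) + (Cz − Cm) exp(−b (t − tz))

- `Cm` (ppm): concentration at equilibrium between chamber and soil/vegetation
  exchange;
- `a` (ppm s⁻¹): residual linear drift at equilibrium;
- `b` (s⁻¹): equilibration rate; values outside [0, 1) are treated as
  optimiser artefacts by QC;
- `Cz` (ppm): concentration at the effective time origin `tz`, with
  C(tz) = Cz identically.

`Cz` is not a free parameter: it is fixed to the ordinary least-squares
intercept of the first 15 s of the retained window, regressing on time
since the window start (regressing on absolute time since closure would
extrapolate the intercept 10 s backwards along a curved series and is
strictly worse). The remaining four parameters (Cm, a, b, tz) minimise
the RMSE of the residuals by Nelder–Mead simplex search (derivative-free,
matching the behaviour class of a default `optim`-style fit), initialised
at Cm = mean of the last 10 readings, a = OLS slope over the whole
window, b = 0.1 s⁻¹, tz = window start, with tight tolerances
(xatol 1e-8, fatol 1e-10). `tz` is unbounded. Non-convergence is
reported as a flag input, never raised.

The flux is the model slope at tz,

    C′(tz) = a + b (Cm − Cz),

stored alongside the parameters (the identity is exact by construction),
converted to an areal molar flux with the ideal-gas factor
P·V/(R·T·A) — P in atm, V chamber+tubing volume in L,
R = 0.082057 L·atm·K⁻¹·mol⁻¹, T the mean chamber air temperature in K,
A the chamber base area in m² — giving µmol m⁻² s⁻¹, scaled by 3.6 to
mmol m⁻² h⁻¹ (the unit of the published flux tables).

### A known bias of the slope estimate

On a noiseless series generated exactly from the model, the fit drives
the RMSE to machine zero, yet the reported slope is **not** the
generating slope unless the series is nearly linear. The reason is
structural: the OLS intercept over the first 15 s of a curved series is
biased by the curvature (≈ −15.2 · b²(Cm − Cz) ppm for this window), and
because `tz` is free the optimiser reproduces the true curve exactly and
reports its slope at the (shifted) point where the curve passes through
the biased Cz. The relative slope error is ≈ 15.2 b² when the
exponential term dominates the drift: below 10⁻³ only for
b ≲ 0.008 s⁻¹, ~0.6 % at b = 0.02, ~3 % at b = 0.05. The validation
batteries therefore report the fraction of noiseless series recovered
within 10⁻³ honestly (well below 1 under the default scenario
distribution, whose b spans 0.002–0.05 s⁻¹ log-uniformly) rather than
hiding the bias by simulating only near-linear closures. Under 2 ppm
Gaussian noise the median relative slope error is ~6 %, dominated by
small-flux scenarios (|C′(tz)| < 0.2 ppm s⁻¹), where any estimator is
noise-limited on a 160 s window.

## Flux QC and partitioning

Each fitted closure receives exactly one flag, evaluated in order:

1. `start_error` — first retained reading outside 421 ± 100 ppm
   (e.g. operator breath); the value is removed.
2. *bad fit* — any of: b ≥ 1 or b < 0 (artefact exits of the plausible
   interval), an ER closure with C′(tz) < 0 (dark uptake is
   non-physical), or optimiser non-convergence.
3. bad fit with |Pearson r(t, C)| > 0.5 on the fitted window →
   `discard` (a real trend the model failed to capture).
4. bad fit with |r| ≤ 0.5 → `zero` (variation is noise; value set to 0).
5. otherwise `okflux` with the converted value.

Boundary conventions: b = 1 is a bad fit (the rule is b ≥ 1); |r| = 0.5
takes the `zero` branch (discard requires strictly > 0.5). `weird_flux`
is an analyst-supplied override list (visual inspection), which replaces
any flag except `missing_round`. Scheduled (plot, round, type) slots
with no measurement receive `missing_round` placeholders, so flag counts
always partition the campaign exactly.

GPP = NEE − ER per plot and round (negative GPP = uptake). Flag
propagation: a zero-flagged NEE yields `zeroNEE` (checked first), a
zero-flagged ER `zeroER`; a value-less member blocks GPP with that
member's flag. CO₂ pooled in the canopy before transparent closures
inflates night-time GPP, so within each site × 24 h cycle (cycles run
from the site's first measurement, not calendar midnight, because
campaigns start mid-day) the most positive valued GPP is subtracted from
all valued GPP. The applied offset is stored per record, flags are
untouched, and the correction applies to GPP only — NEE and ER are
reported as measured. A configuration switch (`night_correction: off`,
or `--no-night-correction`) bypasses the step, leaving GPP = NEE − ER
bit-exact for users who prefer uncorrected data.

## Leaf traits

For multi-leaf samples, wet mass, dry mass and area are divided by the
leaf count to give per-leaf values; when leaves were lost between
weighing and drying, dry mass is divided by the count at the drying
station while wet mass and area keep the original count — each trait
stays internally consistent, and the identity SLA × LDMC = per-leaf
area / per-leaf wet mass holds exactly regardless of leaf loss. The five
tightly folded graminoids (Festuca rubra, F. ovina, F. vivipara,
Avenella flexuosa, Nardus stricta) are scanned folded, so their scanned
area is doubled. Thickness is the mean of up to three micrometer
readings. SLA = per-leaf area / per-leaf dry mass (cm² g⁻¹); LDMC =
per-leaf dry / per-leaf wet mass (g g⁻¹); C:N and N:P are simple ratios
of mass percentages. Chemistry measured on pooled samples is duplicated
onto every member leaf with `merged=True` and the underscore-joined
member list, mirroring the published long-format table.

Validation removes (flags, and drops from the clean view only) values
beyond plausibility limits, all strict inequalities: LDMC > 1 g g⁻¹,
SLA < 5 or > 500 cm² g⁻¹, leaf N > 6.4 % (a literature-derived ceiling
accepted as configuration, not recomputed). Removal is value-level: one
implausible trait does not discard the leaf's other traits. Missing
inputs yield absent values flagged `missing <field>`; machine flags are
appended to, never overwrite, free-text flags from the field sheets.

## Assimilation–temperature curve QC

Curves (leaf temperature vs CO₂ assimilation along a ~33 min ramp logged
every 2 s, so ~990 points) are screened by two criteria:

1. **Modality.** A cubic smoothing spline with the smoothing parameter
   chosen by generalised cross-validation is evaluated on a 512-point
   uniform grid; maxima are counted with plateaus collapsed, boundary
   maxima included, and a prominence requirement of 5 % of the smoothed
   amplitude — GCV leaves sub-noise wiggles on flat curve tops, and a
   wiggle is not a second thermal optimum. More than one maximum
   (e.g. stomatal oscillation) excludes the curve.
2. **Optimum location.** The Sharpe–Schoolfield model with
   high-temperature deactivation, in its explicit-Topt form

       r(T) = r_tref · exp(−E/k (1/T − 1/Tref)) /
              (1 + E/(Ed − E) · exp(Ed/k (1/Topt − 1/T)))

   (T in Kelvin, k = 8.617×10⁻⁵ eV K⁻¹, Tref = 20 °C), is fitted by
   bounded nonlinear least squares with a deterministic multi-start over
   Topt (five starts across the measured range plus one 10 K above it);
   fits with Ed ≤ E are rejected. A fitted Topt strictly below the
   lowest or above the highest measured leaf temperature excludes the
   curve — the data cannot constrain a peak they do not bracket.
   Boundary-equal optima are kept.

Decisions are invariant to positive rescaling of the assimilation axis
(both the spline maxima count, whose prominence is relative, and Topt).
A caveat: when the true optimum lies just beyond the measured range,
noise can fabricate a marginally interior peak, so beyond-range curves
are occasionally kept; at the instrument's native ~990 points per curve
this affects a few percent of such curves at 5 % noise (it was ~15 % in
exploratory runs with series 10× shorter — series length is what buys
the reliability).

## Microclimate

Logger rows are trimmed to the closed deployment interval
[datetime_in, datetime_out]. Values beyond plausibility ranges — air
−40…30 °C, ground −40…35 °C, soil 5…20 °C, moisture < 0 % — are flagged
(`cut_Tmin_*`/`cut_Tmax_*`/`cut_min_moist`), nulled in the raw view and
dropped from the clean view; boundary-equal values are kept (strict
inequalities). Filtering is idempotent. Raw moisture counts are
converted to volumetric % by a user-supplied per-soil-class polynomial
(default class label `silt_loam`); the coefficients are instrument
calibration constants accepted as opaque configuration.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (scenario, seed) and attach ground
truth (generating parameters, intended QC flag) to every record:

- **Flux closures** follow the equilibration model exactly, with
  additive i.i.d. Gaussian noise (default 1 ppm, the infrared analyser's
  noise class; the magnitude is configuration, not measured). Campaign
  scenarios draw b log-uniformly on [0.002, 0.05] s⁻¹ (equilibration
  time constants from 20 s to ~8 min), amplitude Cm − Cz of 10–80 ppm,
  drift 0.005–0.05 ppm s⁻¹, starting concentrations ~N(421, 15) ppm;
  ER closures always release CO₂, NEE closures take either sign. A
  closed failure-mode library maps one-to-one onto QC flags:
  high/low starting concentration → `start_error`; b ≥ 1 with a
  sustained trend → `discard`; a fast transient with no trend → `zero`;
  dark-chamber uptake → `discard`. Diurnal campaigns emit one NEE + ER
  pair per plot and hour with shared covariates and a schedule for
  missing-round accounting.
- **Trait envelopes** draw per-leaf area, SLA, LDMC and leaf chemistry
  in realistic ranges, emit bulk masses and scanned (half for folded
  species) areas, and inject threshold violations at requested rates,
  at most one per sample.
- **AT curves** are generated from the Sharpe–Schoolfield model itself
  (unimodal; the optimum-recovery round trip is exact at zero noise),
  from two separated Gaussian peaks (bimodal), or as a monotone rise
  whose optimum lies beyond the range.
- **Microclimate** series are diurnal sinusoids with labelled
  out-of-range injections.

Not emulated: instrument firmware quirks, clock drift, pressure and
water-vapour effects on the analyser, autocorrelated sensor noise,
within-closure temperature trends, real species trait covariance, and
real AT-curve asymmetries beyond the fitted model family. Passing the
validation batteries therefore demonstrates the *processing* is correct
and self-consistent under the stated noise model — it does not certify
accuracy on field data with artefacts outside these families; the flag
vocabulary and the raw views exist precisely so such cases stay
auditable.

## Validation battery sizes

Chosen for seconds-to-minutes desk runs: 200 closures per slope-recovery
battery (noiseless and 2 ppm); one 12-round, 3-plot, zero-noise campaign
with all failure modes injected at 8 % each and one missing round; 10,000
samples for the trait identity, 800 for threshold recall; 100 AT curves
(interior optima 15–32 °C, exterior 46–55 °C, bimodal, monotone, over
8–40 °C at 5 % noise) and 10 low-noise curves for Topt recovery; two
2-day loggers for microclimate. `scripts/acceptance.py` recomputes all
of them from a single seed.
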