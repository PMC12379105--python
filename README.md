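# fieldflux

Processing and quality-control pipelines for grassland field-campaign
data: closed-chamber ecosystem CO₂ fluxes, leaf functional traits,
leaf assimilation–temperature (AT) response curves, and microclimate
logger series. The package is aimed at ecosystem ecologists who need the
raw instrument output of such a campaign turned into clean, flagged,
analysis-ready tables — and at anyone who wants to audit exactly how
each number and each flag was produced, since every stage can be
exercised end-to-end on simulated data with known ground truth.

## What it computes

**Chamber fluxes.** A chamber closure logs CO₂ (ppm) at 1 Hz for 180 s.
After removing the first and last 10 s, the series is fitted to the
equilibration model

    C(t) = Cm + a (t − tz) + (Cz − Cm) · exp(−b (t − tz))

with Cz fixed to the OLS intercept of the first 15 s of the retained
window and (Cm, a, b, tz) minimising the residual RMSE (Nelder–Mead).
The slope at tz, C′(tz) = a + b (Cm − Cz), is converted to an areal flux

    flux = C′(tz) · P·V / (R·T·A)        [µmol m⁻² s⁻¹, ×3.6 → mmol m⁻² h⁻¹]

Each flux then passes a flag decision tree (implausible start
concentration → `start_error`; artefactual b or dark-chamber uptake,
with/without a time trend → `discard`/`zero`; otherwise `okflux`).
GPP = NEE − ER per plot and round, with per-site diurnal re-baselining
so the most positive GPP of each 24 h cycle is zero.

**Leaf traits.** Per-leaf averaging of wet/dry mass and scanned area
(doubled for folded-leaf graminoids), SLA = area/dry mass, LDMC =
dry/wet mass, C:N and N:P ratios, and plausibility screening
(LDMC > 1 g g⁻¹, SLA outside (5, 500) cm² g⁻¹, N > 6.4 % flagged and
removed from the clean view).

**AT curves.** A GCV-smoothed cubic spline must be unimodal, and the
optimum of a Sharpe–Schoolfield fit (high-temperature deactivation,
explicit-Topt form) must lie inside the measured leaf-temperature range;
otherwise the curve is excluded with a machine-readable reason.

**Microclimate.** Logger series are trimmed to their deployment window
and screened against per-variable plausibility ranges (air −40…30 °C,
ground −40…35 °C, soil 5…20 °C, moisture ≥ 0 %), with the standard
`cut_*` flag vocabulary.

## Worked example

Simulate a one-site diurnal campaign, process it, and summarise flags:

```bash
fieldflux --seed 3 simulate --out sim --n-rounds 4
fieldflux fluxes --in sim/flux_series.csv --schedule sim/schedule.csv --out fluxes.csv
```

which prints the flag report

```
discard: 4
okflux: 32
total: 36
```

i.e. 4 rounds × 3 plots × (NEE, ER, GPP) = 36 records, every one
carrying exactly one flag. The four discards are closures whose
equilibration rate b is too small to identify under the 1 ppm simulated
instrument noise, so the optimiser can land outside [0, 1) — the same
artefact the flag tree is designed to catch on real data. The same can
be done in Python:

```python
from fieldflux import ChamberSpec, flux_from_slope

flux_from_slope(1.0, ChamberSpec(volume_L=25.0, area_m2=0.0625), 293.15)
# 59.86279061776552 mmol m⁻² h⁻¹ — a 1 ppm/s slope, 25 L chamber, 0.0625 m²
```

A trait example: a two-leaf sample with 0.2 g wet mass, 0.05 g dry mass
and 10 cm² scanned area yields per-leaf values (0.1 g, 0.025 g, 5 cm²),
SLA = 200 cm² g⁻¹ and LDMC = 0.25 g g⁻¹.

## Layout

- `fieldflux.chamber` — trimming, Cz estimation, exponential fit, unit conversion
- `fieldflux.fluxqc` — flag decision tree, GPP, diurnal correction, missing rounds
- `fieldflux.traits` — trait derivation, pooled chemistry, validation
- `fieldflux.thermal` — AT-curve modality test and Sharpe–Schoolfield QC
- `fieldflux.microclimate` — deployment trimming, plausibility thresholds
- `fieldflux.synthetic` — seeded generators for every input, with ground truth
- `fieldflux.validation` — recovery/agreement batteries used by tests and the
  acceptance script
- `fieldflux.io`, `fieldflux.config`, `fieldflux.cli` — CSV schemas, YAML
  configuration (committed defaults in `src/fieldflux/default_config.yaml`),
  command-line entry points
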