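chamber:
  pressure_atm: 1.0
  volume_L: 25.0
  area_m2: 0.0625
flux_qc:
  start_center: 421.0
  start_halfwidth: 100.0
  b_max: 1.0
  r_cut: 0.5
traits:
  ldmc_max: 1.0
  sla_min: 5.0
  sla_max: 500.0
  nitrogen_max: 6.4
microclimate:
  air_min: -40.0
  air_max: 30.0
  ground_min: -40.0
  ground_max: 35.0
  soil_min: 5.0
  soil_max: 20.0
  moisture_min: 0.0
folded_species:
- Avenella flexuosa
- Festuca ovina
- Festuca rubra
- Festuca vivipara
- Nardus stricta
night_correction: true
trim_head_s: 10.0
trim_tail_s: 10.0
cz_window_s: 15.0
seed: 0
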