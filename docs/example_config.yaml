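# Example end-to-end pipeline configuration for `sedgeflux run-all`.
# Every stage is optional: omit `chamber`/`fit` to supply q10 directly,
# omit `met` to stop after the fit.
seed: 1
output_dir: sedgeflux_out

chamber:
  # either `path: chamber.csv` (raw chamber records) or a simulation:
  simulate:
    true_q10: 7.2
    e_ref: 2.0          # nmol m-2 s-1 at 30 degC
    t_min: 20.0         # degC
    t_max: 35.0
    n_points: 30
    noise_cv: 0.05

fit:
  t_ref: 30.0           # degC, normalization temperature
  t_fit_max: 35.0       # degC, stability cutoff (inclusive)
  method: ols           # or nls
  ci_method: normal     # or bootstrap
  n_boot: 1000

met:
  # either a MesoWest-style CSV with declared units ...
  #   path: met.csv
  #   timestamp_column: Date_Time
  #   temperature_column: air_temp
  #   light_column: solar_radiation
  #   units: {temperature: C, light: shortwave}
  # ... or a synthetic baseline + heat wave:
  simulate:
    n_days_baseline: 10
    n_days_heatwave: 5
    t_mean_baseline: 295.0   # K
    t_amplitude: 7.0         # K
    t_boost_heatwave: 8.0    # K
    ppfd_max: 1500.0         # umol m-2 s-1
    timestep: 30             # minutes

species:
  # an exponential species without q10 inherits the fitted value
  - {name: sedge, emission_factor: 2.0, lai: 1.5, response: exponential}
  - {name: tree, emission_factor: 2.0, lai: 1.5, response: megan_default}

# MEGANv2.1 isoprene coefficient overrides (values ship as published
# MEGANv2.1 defaults; override only for sensitivity studies), e.g.:
# megan_overrides: {eopt_base: 2.034}

# periods default to the synthetic heat-wave markers; with real met data
# supply them explicitly (half-open [start, end), station local time):
# periods:
#   - {label: baseline, start: 2022-08-15, end: 2022-08-31}
#   - {label: heatwave, start: 2022-08-31, end: 2022-09-10}

daytime_only: false
trim_spinup_days: 0
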