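# growthkin

Batch growth-curve kinetics for bubble-column photobioreactor (PBR)
campaigns. The package covers the full analysis chain for optical-density
time series recorded under different aeration intensities:

- **preprocessing** — OD750 → biomass calibration (`X = OD · k_cal · n`),
  warning on out-of-range absorbances, and volume correction of measured
  concentrations against an evaporation/top-up ledger;
- **models** — forward evaluation of five time-course growth models
  (logistic, logistic with lag, modified Gompertz, Baranyi–Roberts, and a
  linear+logistic two-phase model stitched continuously at a transition
  time `t_s`) plus an aeration–temperature rate surface
  (Monod saturation in vvm × Gaussian temperature optimum);
- **transition** — change-point detection of the linear→logistic
  transition: OLS line on an early window, extrapolation, and a
  mean + k·SD threshold on absolute deviations;
- **fitting** — bounded trust-region nonlinear least squares with
  data-driven initial guesses, R²/RMSE goodness of fit, and a multi-model
  comparison table per reactor;
- **surface** — per-reactor initial slopes (first 100 h), mean
  temperatures, L/min → vvm conversion, and the four-parameter surface fit
  with identifiability diagnostics;
- **simulate** — seeded synthetic campaigns (8 reactors, 700 h,
  daily-then-irregular sampling, evaporation and top-ups, multiplicative
  observation noise) with ground truth returned for recovery testing;
- **pipeline/CLI** — end-to-end orchestration with deterministic seeding
  and JSON/CSV artifacts.

## CLI

```sh
# generate a synthetic campaign (one CSV per reactor + ground_truth.json)
growthkin simulate --config reactors.yaml --out campaign/ --seed 1

# individual stages
growthkin preprocess --input campaign/PBR5.csv --out corrected.csv --evaporation-ml-per-h 1.5
growthkin detect     --input campaign/PBR5.csv --window 92 --ksd 2
growthkin fit        --input campaign/PBR5.csv --model hybrid_two_phase
growthkin compare    --input campaign/ --models logistic,gompertz,baranyi_roberts,hybrid_two_phase
growthkin surface    --input campaign/ --config reactors.yaml

# everything at once
growthkin run-all --config pipeline.yaml --seed 1
```

`reactors.yaml` lists the reactors:

```yaml
reactors:
  - {reactor_id: PBR1, airflow_L_min: 1.0, working_volume_L: 4.0}
  - {reactor_id: PBR2, airflow_L_min: 2.0, working_volume_L: 4.0}
```

A full pipeline config additionally accepts `models`, `noise_cv`,
`duration_h`, `evaporation_mL_per_h`, `detection_window_h`,
`detection_k_sd`, `surface_t_max_h`, `out_dir`, and `seed`; see
`growthkin.pipeline.RunConfig`.

## Input CSV schema

Comma-separated with header:
`reactor_id,time_h,od750,dilution_factor,temperature_C,added_mL`
(temperature and top-up volume may be blank). Time is hours since
inoculation and must be strictly increasing.

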