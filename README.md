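# readry

Lumped activated-evaporation (reaction-engineering-approach) drying model
for grain batches, with first-class support for intermittent
drying/tempering schedules.

The package covers the full pipeline around a single idea: evaporation from
a moist grain batch is an activated process whose surface relative humidity
is `RH_s = exp(-dEv / (R T_s))`, where the apparent activation energy `dEv`
is a material "fingerprint" — a cubic in the free moisture content
`X - X_b` — scaled by the equilibrium activation energy
`-R T_b ln(RH_b)` of the ambient air.

Modules:

- **`readry.physics`** — psychrometrics (saturated/bulk vapor
  concentration), dry-air property correlations (fits to the Incropera &
  DeWitt 1-atm table), and forced-convection transfer coefficients
  (`Sh = 0.511 Re^0.5 Sc^0.37`, `Nu = 0.511 Re^0.5 Pr^0.37`).
- **`readry.rea_core`** — the model proper: activation-energy laws, coupled
  moisture/temperature balances, and `simulate()`, which integrates them
  phase-by-phase over a schedule (adaptive stiff-capable solver, hard
  restarts at ambient steps, optional moisture-target stop event, full
  per-sample diagnostics).
- **`readry.schedule`** — drying/tempering schedules, the intermittency
  `alpha = t_D / (t_D + t_T)`, and total-vs-operating drying-time
  accounting with interpolated target crossing.
- **`readry.calibration`** — the inverse pipeline: per-sample activation
  energies from a measured curve (noise-robust adaptive Savitzky-Golay
  differentiation), normalization, and OLS cubic fitting with R²/RMSE.
- **`readry.synthetic_data`** — noisy synthetic drying experiments with
  known ground truth (emulating a ~30 g soybean batch dried at
  35 °C / 20 % RH / 3 m/s with 25 °C / 43 % RH tempering), cracking-ratio
  bookkeeping, and reference benchmark fixtures.
- **`readry.io_cli`** — curve CSV dialect (seconds / grams / Kelvin),
  TOML/JSON run configuration, and the `readry` command-line tool.

## CLI

```sh
# forward-simulate the default continuous run, write curve + summary
readry simulate --config run.toml --out curve.csv --summary summary.json

# generate a synthetic experiment with ground truth
readry synth --seed 1 --out-dir synth/

# recover the activation-energy fingerprint from a measured/synthetic curve
readry calibrate synth/measured.csv --out fingerprint.json

# compare the four intermittency schemes (alpha = 1, 0.5, 0.4, 0.25)
readry report
```

All subcommands accept `--config` (TOML or JSON, merged over documented
defaults; temperatures are given in Celsius via explicit `_C` keys). See
`readry.io_cli.DEFAULT_CONFIG` for the full schema, e.g.:

```toml
[schedule]
t_D_s = 600.0      # drying period per cycle
t_T_s = 1800.0     # tempering period per cycle (0 = continuous)
max_total_s = 200000.0

[targets]
X_target_db = 0.134
```

## Notes on defaults

The default material/geometry emulate a single-layer ~30 g soybean batch
(X0 = 0.25 kg/kg d.b., T0 = 25 °C, X_b = 0.06 kg/kg). The exchange area is
an *effective* lumped parameter tuned so the default continuous run reaches
the 0.134 kg/kg shelf-life target on the ~30,000 s scale typical of such
experiments; every default is overridable in the config. The cracking
percentages bundled in `reference_fixtures()` are experimental benchmark
values for report tables, never model outputs.
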