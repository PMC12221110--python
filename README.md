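# tado2i

Temperature-adjusted indexed oxygen delivery (DO₂i) targets for
cardiopulmonary bypass (CPB).

Static goal-directed-perfusion thresholds (~280–300 mL/min/m²) ignore the
temperature dependence of metabolic demand. This package implements three
temperature-dependent models of the critical DO₂i and scales them by body
surface area (BSA) to give individualized oxygen-delivery targets:

- **Q10 exponential model** — `baseline · q10^((T_ref − T)/10)` with a
  decay factor (default 0.6 per 10 °C, baseline 300 mL/min/m² at 37 °C);
- **linear model** — a fixed fractional reduction per °C below
  normothermia (default 6 %/°C);
- **calibrated quadratic** — `DO₂i = 0.057·T² + 10.754·T − 194.245`
  (per m²), the temperature-adjusted target, multiplied by BSA for the
  patient-specific total (taDO₂i, mL/min).

Alongside the closed-form models it provides:

- **calibration** — quadratic least squares on `(temperature, DO₂i)` data
  with R², standard error of estimate (residual df = n − 3), and seeded
  case-resampling percentile bootstrap confidence intervals;
- **synthetic** — seeded generation of calibration datasets (Q10, linear,
  quadratic, or blended mean curve + Gaussian noise) on a 24–37 °C grid;
- **trajectory** — per-model target trajectories over time/temperature
  profiles, model-comparison tables, and a pump-flow helper based on the
  standard arterial oxygen content `CaO₂ = 1.36·Hb·(SaO₂/100) + 0.003·PaO₂`;
- a **CLI** (`tado2i`) exposing all of the above.

Models are valid over 24–37 °C (the calibration span); outside it they
raise an error unless extrapolation is explicitly enabled, which downgrades
the error to a warning. Computation is full precision; one-decimal rounding
is applied only for display.

## CLI

```sh
# single target: per-m² and BSA-scaled total
tado2i target --temp 30 --bsa 1.8 --model quadratic
tado2i target --temp 28 --height 180 --weight 75 --model all

# model-comparison table
tado2i table --temps 25,28,30,33,35,37 --bsa 1.8

# targets along a bypass temperature profile (CSV: time_min,temp_c)
tado2i trajectory profile.csv --bsa 1.8 --format json

# synthesize a calibration dataset and refit it
tado2i synth --seed 42 --out data.csv
tado2i calibrate data.csv --resamples 1000 --seed 7
tado2i synth --seed 42 | tado2i calibrate - --resamples 1000 --seed 7
```

Exit codes: 0 success, 2 usage error, 3 domain/range error, 4 I/O or parse
error. An optional TOML config (`tado2i --config cfg.toml …`) can override
model parameters; command-line flags win. `-v` logs effective parameters to
stderr.

## Layout

```
src/tado2i/
  models.py       closed-form models, BSA formulas, display rounding
  calibration.py  quadratic OLS, bootstrap CIs, CSV/JSON I/O
  synthetic.py    seeded synthetic calibration datasets
  trajectory.py   profiles, trajectories, comparison tables, flow helper
  cli.py          click front end
tests/            pytest suite; test_acceptance.py covers the acceptance criteria
scripts/acceptance.py
```
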