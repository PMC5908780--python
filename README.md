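# hfovbench

Simulator and analysis pipeline for a high-frequency oscillatory ventilation
(HFOV) bench experiment: a sinusoidal oscillator driving a well-mixed 20-L
test lung with continuous CO₂ insufflation, circuit gas mixing with bias-flow
dilution and rebreathing, and the full measurement chain — stroke-volume
extraction by flow integration, steady-state CO₂ mass-balance estimation of
alveolar ventilation, ventilation-efficiency indices, curve fits (linear /
power / exponential / quadratic) and one-way ANOVA with Tukey's HSD.

All data are synthetic: the simulator emits flow traces (200 Hz), capnometer
PCO₂ traces, and analytic ground truth for every run, so the whole pipeline
is testable offline.

## Modules

| module | contents |
| --- | --- |
| `hfovbench.circuit_core` | pure closed-form ops: minute ventilation, alveolar-ventilation estimators, bias-flow rebreathing/dilution relations, required-BF algebra, gas-compression compliance |
| `hfovbench.synthetic_bench` | per-cycle bench simulator, flow/PCO₂ trace generation, study grids, calibration, trace file I/O |
| `hfovbench.sv_measurement` | per-second expiratory stroke volume by trapezoidal integration of the flow signal, 60-s averaging |
| `hfovbench.washout_analysis` | VCO₂ calibration inversion, stabilized-PCO₂ detection, per-condition results tables |
| `hfovbench.stats_fits` | fit families with signed linearized correlations and p-values; one-way ANOVA + Tukey HSD |
| `hfovbench.cli_io` | `hfovbench` CLI: config parsing, manifests, report files |

## CLI

```sh
# simulate a configured grid: traces + truth table + manifest
hfovbench simulate --config config.yaml --out out/sim

# analyze a trace directory: results / fits / ANOVA reports
hfovbench analyze --traces out/sim --config config.yaml --out out/reports

# built-in study designs with figure-analog tables and worked-example checks
hfovbench reproduce --study 1 --out out/study1 --seed 0
hfovbench reproduce --study 2 --out out/study2 --seed 0
```

Study 1 sweeps setting stroke volume 80–180 mL (10 mL steps) at bias flows
10/20/30/40 L/min (n = 5); study 2 targets actual stroke volumes 80/100/120 mL
at bias flows 10–60 L/min. `reproduce` exits non-zero if any built-in
consistency check fails.

A config file is a YAML document (`schema: hfovbench-config-v1`) with
optional sections `settings`, `lung`, `gas`, `mixing`, `attenuation`,
`transport`, `sim`, `grid`, `stabilization`; unknown keys are rejected with
their field path. All omitted keys take the defaults shown in the dataclasses.

## Notes on conventions

* The alveolar-ventilation estimator used in result tables is the literal
  ratio VCO₂ (mL/min) / PCO₂ (mmHg) reported as L/min (the study's reporting
  scale); a pressure-explicit variant (`va_physiological`) is carried as an
  extra column.
* The per-cycle alveolar exchange volume
  `V_alv = c1·max(aSV − VD, 0) + c2·aSV^p` is a declared non-physiological
  stand-in; coefficients live in `TransportParams` and are config-visible.
* The 20-L container's gas-compression compliance matches the isothermal
  formula (19.36 mL/cmH₂O at 760 mmHg); both isothermal and adiabatic modes
  are provided.
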