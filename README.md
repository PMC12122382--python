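# tsbdecay

Patient-specific modelling of total serum bilirubin (TSB) dynamics in very
preterm infants (24–32 weeks of gestation).

After the first days of life, TSB in preterm neonates declines towards a
low baseline as the bilirubin-conjugation pathway matures. Routine-care TSB
draws trace this decay sparsely (typically 4–20 samples per infant, starting
after 72 h of life). `tsbdecay` fits each infant's trajectory with a
gestational-age-shifted exponential decay,

```
y_i(t) = A_i · exp(−B_i · [p_i(t) + GA_i + Tc_i]) + C_i + ε_i
```

where `p_i(t)` is postnatal age (days), `GA_i` gestational age at birth
(days), `A_i` an amplitude (µmol/L), `B_i` the decay rate (1/day), `C_i`
the baseline asymptote (µmol/L), and `Tc_i` a patient-specific time
correction (days) that, together with GA, shifts the curve along the time
axis. Parameters are estimated by bounded robust nonlinear least squares
(`A ∈ [0, 200]`, `B ∈ [0, 1.5]`, `C ≥ 0`) over a deterministic grid of
start points and smooth-L1 robustness configurations, selecting the
candidate with the lowest sum of squared residuals. Because `A` and `Tc`
enter the curve only through the composite amplitude
`Ã = A · exp(−B · (GA + Tc))`, recovery claims are made for `(Ã, B, C)`.

Around the curve fit the package provides:

- a **synthetic cohort generator** reproducing the cohort structure this
  kind of study assumes (parameter and sampling-schedule distributions,
  phototherapy intervals, injected morbidity episodes with elevated CRP),
  with full ground truth for recovery and detection experiments;
- the **inclusion cascade** that selects modellable infants: ≥ 4 TSB
  samples, no adjacent samples more than 10 days apart, removal of samples
  drawn during phototherapy or exchange transfusion with a re-check;
- **population analysis**: parameter summaries and histograms, the median
  model, one-at-a-time local sensitivity sweeps, Pearson correlation,
  chi-square / Mann–Whitney cohort comparisons with Bonferroni correction;
- **event association**: elevated-CRP counting in the post-phototherapy
  window, the RMSE-vs-CRP association table with a Spearman rank
  correlation, and a deviation alert that flags a new TSB measurement
  further than `max(2·RMSE, 10 µmol/L)` from the expected decay.

Intended users are researchers in neonatal biostatistics who want a tested,
reproducible implementation of this modelling pipeline to run on their own
cohort CSVs or on synthetic data.

## Worked example

```python
from tsbdecay import GeneratorSettings, generate_cohort, fit_patient
from tsbdecay.models import eval_patient_specific

settings = GeneratorSettings(n_patients=3, seed=7, event_fraction=0.0,
                             pt_fraction=0.0)
cohort, truth = generate_cohort(settings)
patient = cohort[0]
fit = fit_patient(patient)
print(f"patient {patient.patient_id}: GA {patient.ga_days/7:.1f} weeks, "
      f"{len(patient.measurements)} TSB samples")
print(f"  A  = {fit.params.a:7.2f} umol/L")
print(f"  B  = {fit.params.b:7.4f} /day")
print(f"  Tc = {fit.params.tc:7.1f} days")
print(f"  RMSE = {fit.rmse:.2f} umol/L")
```

prints

```
patient S0000: GA 29.0 weeks, 7 TSB samples
  A  =  107.15 umol/L
  B  =  0.2970 /day
  Tc =  -210.2 days
  RMSE = 1.92 umol/L
```

The infant's TSB halves roughly every `ln 2 / 0.297 ≈ 2.3` days; the large
negative `Tc` compensates the ~203-day gestational age inside the exponent
(their sum, `GA + Tc ≈ −7` days, is the effective time shift). The RMSE of
1.9 µmol/L says the decay curve explains the observations to within about
2 µmol/L — an unremarkable, well-monitored trajectory. A later measurement
far above `eval_patient_specific(fit.params, pna)` would raise a deviation
alert (`tsbdecay.events.deviation_alert`).

## Command-line pipeline

```sh
tsbdecay simulate --n 72 --seed 42 --out cohort/
tsbdecay run --cohort-dir cohort/ --out results/ --seed 42
```

writes `filter_report.csv`, `fits.csv`, `summary.csv`, `median_model.csv`,
`sensitivity_{A,B,C,Tc}.csv`, `associations.csv` and a JSON manifest with
per-stage row counts. All tunables (bounds, thresholds, generator
distributions) live in a flat `key: value` config file passed with
`--config`; defaults are documented in `tsbdecay.io.RunConfig`.

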