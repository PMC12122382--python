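# Methods

## The model

The central object is a patient-specific exponential decay for total serum
bilirubin (TSB) in very preterm infants,

```
y_i(t) = A_i · exp(−B_i · [p_i(t) + GA_i + Tc_i]) + C_i + ε_i ,
```

with postnatal age `p_i(t)` in days, gestational age at birth `GA_i` in
days, amplitude `A_i` (µmol/L), decay rate `B_i` (1/day), asymptote `C_i`
(µmol/L), time correction `Tc_i` (days) and measurement error `ε_i`. The
model assumes first-order elimination towards a stable baseline: after
physiological jaundice peaks, the decline rate is proportional to the
distance from the baseline `C`. Two simpler population curves — a linear
trend `A + B·t` and a plain exponential `A·exp(−B·t) + C` — are provided
for pooled-sample comparison; the patient-specific curve differs from the
latter only by the `GA + Tc` time shift, which lets one curve family
express trajectories caught at different maturational phases.

**Identifiability.** `A` and `Tc` enter the mean only through
`Ã = A · exp(−B · (GA + Tc))`; any `(A, Tc)` pair on that gauge orbit gives
the same curve. The package therefore reports raw `(A, B, C, Tc)` (bounded,
so the fitted representative is well defined) *and* the composite
`(Ã, B, C)`, and makes recovery claims only about the composite set. This
is also why `Tc` is always large and negative: with `GA ≈ 200` days, the
combined shift `GA + Tc` must land back in the order of days for the
curve's knee to fall inside the observation window.

## Fitting

Per patient, bounded nonlinear least squares (scipy's trust-region
reflective solver) on `(A, B, C, δ)` with `δ = GA + Tc`; optimizing `δ`
(order of days) instead of raw `Tc` (order of −200 days) conditions the
problem. Bounds: `A ∈ [0, 200]` and `B ∈ [0, 1.5]` as the model prescribes;
the half-open `C ∈ [0, ∞)` and unbounded `Tc` are given finite boxes
`C ∈ [0, 500]` µmol/L and `δ ∈ [−100, 100]` days — comfortably containing
every plausible fitted value — because the solver needs finite boxes.

The candidate grid:

1. **Plain phase.** Ordinary least squares from 36 deterministic start
   points: `A₀ ∈ {min(max y, 200), 120}`, `B₀ ∈ {0.05, 0.11, 0.3}`,
   `C₀ ∈ {0, min y}`, `δ₀ ∈ {0, −20, +20}`.
2. **Robust phase.** A smooth-L1 ("soft-L1") loss,
   `ρ(z) = 2(√(1+z) − 1)` — a smooth approximation to absolute-error
   regression — at scales `{0.5, 1, 2, 4} × MAD` of the best plain fit's
   residuals, warm-started from the deduplicated plain-phase minima
   (at most 6, ordered by SSR). Warm-starting from converged minima covers
   the same basins as re-running the full raw start grid at a fraction of
   the solver calls.
3. **Selection.** Every candidate is scored by its *plain* (unweighted) sum
   of squared residuals and the lowest wins; ties break on the fixed
   enumeration order (loss family, scale, start index). The procedure is
   fully deterministic.

Because selection is by plain SSR, the robust candidates act mainly as
extra, differently-shaped descent paths; a caller who wants the genuinely
outlier-resistant curve (e.g. to visualize the decay "through" a morbidity
spike) can restrict `FitSettings.loss_families` to `("soft_l1",)` and pin a
scale. Tolerances are `ftol = xtol = gtol = 1e−10` with at most 2000
function evaluations per candidate — tight enough that zero-noise fits
reach the truth to ~1e−11 relative.

Degenerate inputs behave sensibly: a constant series `y ≡ k` is fitted
exactly (`A = 0, C = k`); fewer than 4 samples is a precondition error
(the inclusion cascade should have excluded the patient); if every
candidate fails the result carries `converged = False`.

## Inclusion cascade

Order: minimum-sample check (≥ 4), monitoring-gap check (every adjacent
pair ≤ 10 days apart; *strictly* larger gaps fail), then removal of samples
inside treatment intervals (closed `[start, end]`: a draw at treatment
cessation still reflects treatment effect) with a re-check of the minimum.
First failing rule becomes the single `primary_reason`. The gap rule is
evaluated on the full record by default — infrequent monitoring is a
property of the observation record — but `gap_check_stage = post_strip` is
available since the alternative reading is defensible.

## Synthetic cohort generator

Real cohorts of this kind are not publicly shareable, so experiments run on
generated ones. Defaults emulate the descriptive statistics of a modelled
subgroup of 72 infants born at 24–32 weeks:

| quantity | distribution | anchors |
|---|---|---|
| GA at birth | Uniform[168, 224) days | the 24–32-week study window |
| A | Normal(120.9, 27.54) truncated to [0, 200] | reported mean (SD) |
| B | LogNormal, median 0.11, log-σ = ln(0.21/0.06)/1.349, truncated at 1.5 | reported median [IQR] |
| C | 0 with prob. 0.75, else Exponential(mean 35) truncated at 175 | reported pile-up at 0 and maximum ≈ 171 |
| δ = GA + Tc | Normal(0, 10 days) | reported Tc mean ≈ −(mean GA in days); SD chosen as a plausible maturational spread |
| noise SD | Gamma, moment-matched to mean 10.62, SD 7.69 µmol/L | reported RMSE distribution |
| samples/infant | {4: 0.30, 5: 0.35, 6: 0.15} + geometric tail (ratio 0.65) to 20 | reported median [IQR] of 5 [4, 6], range 4–20 |
| first draw | LogNormal median 4.3 d (quartile-matched to [2, 7]), clipped ≥ 3 | reported first-sample statistics; inclusion starts at 72 h |
| inter-draw gaps | LogNormal median 2 d (log-σ 0.6), clipped to [0.25, 10] | keeps default cohorts inside the 10-day monitoring rule |

The C-mixture's exponential mean (35 µmol/L), the δ and gap spreads, and
the event/bump shapes are the generator's own choices, made once to respect
the printed ranges; they are not fitted to anything.

Morbidity episodes are Gaussian-shaped additive TSB bumps (amplitude
U(40, 120) µmol/L, centre U(10, 30) days shifted into the observed span if
needed, width U(1.5, 4) days) with one co-occurring CRP record
> 5 mg/L within ±2 days of the centre, clamped into the TSB span so the
post-hoc CRP window always contains it. Every patient additionally gets
0–2 baseline CRP draws below 5 mg/L. Phototherapy, when simulated
(default 15% of patients), is an early short interval acting purely as a
sample-removal marker. Negative simulated TSB values are clipped to 0 and
counted.

Reproducibility: per-patient RNG substreams are keyed by `(seed, index)`,
so enlarging a cohort never reshuffles earlier patients; event and
phototherapy assignment use exact counts (`round(fraction · n)`) from a
separate master stream.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: the first 72 h of life, phototherapy
pharmacodynamics (treatment intervals only mark samples for removal),
physiological rebounds other than the injected Gaussian bump,
non-Gaussian or heteroscedastic assay noise, informative sampling (real
draws cluster when clinicians are worried), and any correlation between
GA and the decay parameters. Recovery and detection results on synthetic
cohorts are statements about the estimator under the model's own
assumptions, not clinical validation.

## Experiment design choices

- **Zero-noise / noisy recovery** use dense fixed-length schedules (30 and
  20 samples) with events and treatments disabled: they measure the
  estimator, and sample stripping or bumps would confound the measurement.
  Noisy recovery keeps the default per-patient noise distribution.
- **Noise-floor consistency** uses 50 samples at fixed 0.5-day gaps and
  σ = 8 µmol/L. The dense, short (~3–28 d) schedule keeps the decay tail
  well above the non-negativity clip for typical parameters; clipped
  observations would violate the additive-Gaussian premise the
  `median RMSE ≈ σ·√(1 − 4/n)` consistency band assumes. The expected
  ratio at n = 50 is ≈ 0.96 with mild downward pressure from the 4 fitted
  parameters.
- **Event detection** uses 72 patients with exactly 12 injected episodes
  per replicate and treatments disabled (the CRP window then spans the full
  TSB record for every patient, isolating the association being tested).
- The **median model** needs a GA to be evaluable; the median GA of the
  fitted patients is used (configurable). Sensitivity sweeps default to
  A ∈ [0, 400], B ∈ [0, 0.3], C ∈ [−100, 200], Tc ∈ [−215, −150] on a PNA
  grid of 0–60 days × 0.25 days; sweep ranges deliberately exceed the
  fitting bounds to show extrapolated behaviour.
- **Comparison statistics**: Mann–Whitney U uses the exact null when the
  smaller group has ≤ 8 observations and no cross-group ties, otherwise the
  tie-corrected normal approximation; chi-square applies Yates' continuity
  correction for 2×2 tables; the Bonferroni divisor is an explicit argument
  (`0.05 / 20 = 0.0025` in the canonical configuration). Quartiles use
  linear interpolation (type 7); histogram bins are Freedman–Diaconis with
  a Sturges fallback when the IQR collapses (C piles up at 0).

## Known limitations

- The deviation-alert rule `max(2·RMSE, 10 µmol/L)` is a pragmatic default,
  not a clinically validated threshold.
- Fits are independent per infant; no information is pooled across the
  cohort (no hierarchical shrinkage), and no parameter uncertainty
  intervals are produced.
- Raw `A` and `Tc` are reported as the bounded-solver representative of
  their gauge orbit; comparing raw `A` or `Tc` across patients conflates
  gauge with substance — use `Ã` and `B`.
- The RMSE–CRP association is quantified per patient (count of elevated
  CRPs in the window, Spearman rank correlation against RMSE); other
  aggregations of the same data are possible and would give different
  numbers.
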