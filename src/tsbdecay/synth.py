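"""Synthetic preterm-infant cohort generator.

Real TSB follow-up data for this population are not publicly shareable, so
the package carries a generator that reproduces the statistical structure
the analysis assumes: per-infant exponential-decay trajectories with
additive Gaussian measurement noise, sparse routine-care sampling schedules
(4-20 draws, first after 72 h of life), phototherapy intervals, and injected
morbidity episodes — a transient Gaussian-shaped TSB rebound with a
co-occurring elevated CRP — together with the ground truth needed for
parameter-recovery and event-detection experiments.

Default parameter distributions are anchored to the descriptive statistics
of a modeled cohort of 72 infants born at 24-32 weeks of gestation:
amplitude A ~ N(120.9, 27.54) truncated to [0, 200]; decay rate B
log-normal with median 0.11 and quartiles 0.06/0.21, truncated to (0, 1.5];
asymptote C a 0.75 point mass at zero mixed with a truncated exponential;
combined time shift GA+Tc ~ N(0, 10 d); per-patient noise SD gamma with
mean 10.62 and SD 7.69 µmol/L.

Reproducibility: one master seed; per-patient substreams are keyed by
(seed, patient index) so enlarging the cohort never reshuffles earlier
patients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import CrpMeasurement, PatientRecord, TreatmentInterval, TsbMeasurement
from .io import RunConfig
from .models import DecayParameters, eval_patient_specific

__all__ = [
    "GeneratorSettings",
    "PatientTruth",
    "SyntheticTruth",
    "EventSpec",
    "ConfigurationError",
    "sample_patient_parameters",
    "generate_schedule",
    "simulate_trajectory",
    "inject_event",
    "generate_cohort",
]

log = logging.getLogger(__name__)

#: conversion from a quartile span to the SD of the underlying normal
_IQR_TO_SIGMA = 2.0 * stats.norm.ppf(0.75)  # 1.349...


class ConfigurationError(Exception):
    """Degenerate or infeasible generator settings."""


@dataclass
class GeneratorSettings:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_patients: int = 72
    seed: int = 0

    # gestational age, uniform over 24 to <32 completed weeks (days)
    ga_min_days: float = 168.0
    ga_max_days: float = 224.0

    # amplitude A: truncated normal on [a_min, a_max]
    a_mean: float = 120.9
    a_sd: float = 27.54
    a_min: float = 0.0
    a_max: float = 200.0

    # decay rate B: log-normal (median, quartiles), truncated to (0, b_max]
    b_median: float = 0.11
    b_q1: float = 0.06
    b_q3: float = 0.21
    b_max: float = 1.5

    # asymptote C: point mass at 0 + truncated exponential
    c_zero_fraction: float = 0.75
    c_exp_mean: float = 35.0
    c_trunc: float = 175.0

    # combined time shift delta = GA + Tc ~ N(0, delta_sd_days)
    delta_sd_days: float = 10.0

    # per-patient noise SD: gamma moment-matched to (noise_mean, noise_sd)
    noise_mean: float = 10.62
    noise_sd: float = 7.69
    noise_sd_fixed: Optional[float] = None  # override: exact SD for all patients

    # sampling schedule
    n_samples_min: int = 4
    n_samples_max: int = 20
    count_pmf_456: tuple = (0.30, 0.35, 0.15)  # P(n=4), P(n=5), P(n=6)
    count_tail_ratio: float = 0.65             # geometric decay over 7..max
    first_pna_median: float = 4.3
    first_pna_q1: float = 2.0
    first_pna_q3: float = 7.0
    first_pna_min: float = 3.0                 # inclusion starts at PNA > 72 h
    gap_median_days: float = 2.0
    gap_sigma: float = 0.6
    gap_min_days: float = 0.25
    schedule_max_gap_days: float = 10.0
    # deterministic overrides (used for degenerate/zero-noise experiments)
    n_fixed: Optional[int] = None
    first_pna_fixed: Optional[float] = None
    gap_fixed: Optional[float] = None

    # morbidity events
    event_fraction: float = 1.0 / 6.0
    event_amplitude_range: tuple = (40.0, 120.0)
    event_center_range: tuple = (10.0, 30.0)
    event_width_range: tuple = (1.5, 4.0)
    event_crp_range: tuple = (20.0, 300.0)

    # baseline (non-elevated) CRP draws for every patient
    baseline_crp_max_draws: int = 2
    baseline_crp_range: tuple = (0.0, 5.0)

    # phototherapy intervals (sample-removal markers only)
    pt_fraction: float = 0.15
    pt_start_range: tuple = (3.0, 5.0)
    pt_duration_range: tuple = (0.5, 2.0)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.a_sd <= 0 or not (self.a_min < self.a_max):
            raise ConfigurationError("degenerate amplitude settings")
        if not (0 < self.b_q1 < self.b_median < self.b_q3):
            raise ConfigurationError("B quartiles must satisfy 0 < q1 < median < q3")
        if not 0.0 <= self.c_zero_fraction <= 1.0:
            raise ConfigurationError("c_zero_fraction must lie in [0, 1]")
        if self.c_exp_mean <= 0 or self.c_trunc <= 0:
            raise ConfigurationError("degenerate C settings")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise ConfigurationError("event_fraction must lie in [0, 1]")
        if self.noise_sd_fixed is None and (self.noise_mean <= 0 or self.noise_sd <= 0):
            raise ConfigurationError("noise moments must be positive")
        if not self.n_samples_min <= self.n_samples_max:
            raise ConfigurationError("n_samples_min must be <= n_samples_max")
        n_max = self.n_fixed if self.n_fixed is not None else self.n_samples_min
        if self.gap_min_days * (n_max - 1) > 1000.0:
            raise ConfigurationError("infeasible schedule constraints")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "GeneratorSettings":
        return cls(
            n_patients=cfg.n_patients,
            seed=cfg.seed,
            ga_min_days=cfg.ga_min_days,
            ga_max_days=cfg.ga_max_days,
            a_mean=cfg.a_mean,
            a_sd=cfg.a_sd,
            a_max=cfg.a_max,
            b_median=cfg.b_median,
            b_q1=cfg.b_q1,
            b_q3=cfg.b_q3,
            b_max=cfg.b_max,
            c_zero_fraction=cfg.c_zero_fraction,
            c_exp_mean=cfg.c_exp_mean,
            c_trunc=cfg.c_trunc,
            delta_sd_days=cfg.delta_sd_days,
            noise_mean=cfg.noise_mean,
            noise_sd=cfg.noise_sd,
            first_pna_median=cfg.first_pna_median,
            first_pna_q1=cfg.first_pna_q1,
            first_pna_q3=cfg.first_pna_q3,
            first_pna_min=cfg.first_pna_min,
            gap_median_days=cfg.gap_median_days,
            gap_sigma=cfg.gap_sigma,
            gap_min_days=cfg.gap_min_days,
            schedule_max_gap_days=cfg.schedule_max_gap_days,
            n_samples_min=cfg.n_samples_min,
            n_samples_max=cfg.n_samples_max,
            event_fraction=cfg.event_fraction,
            event_amplitude_range=tuple(cfg.event_amplitude_range),
            event_center_range=tuple(cfg.event_center_range),
            event_width_range=tuple(cfg.event_width_range),
            event_crp_range=tuple(cfg.event_crp_range),
            pt_fraction=cfg.pt_fraction,
        )


@dataclass(frozen=True)
class EventSpec:
    """A Gaussian-shaped additive TSB rebound."""

    center_pna: float
    amplitude: float
    width: float

    def bump(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((p - self.center_pna) / self.width) ** 2)


@dataclass
class PatientTruth:
    """Ground truth for one generated patient."""

    params: DecayParameters
    noise_sd: float
    event_injected: bool = False
    event_center_pna: Optional[float] = None
    event_amplitude: Optional[float] = None
    event_width: Optional[float] = None
    n_clipped: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort, keyed by patient_id."""

    patients: dict = field(default_factory=dict)
    settings: Optional[GeneratorSettings] = None

    def __getitem__(self, patient_id: str) -> PatientTruth:
        return self.patients[patient_id]


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def truncnorm_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of N(mean, sd) truncated to [lo, hi] (used by distribution checks)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def sample_patient_parameters(
    rng: np.random.Generator, settings: GeneratorSettings, ga_days: float
) -> tuple[DecayParameters, float]:
    """Draw one patient's true decay parameters and noise SD.

    All truncated draws use inverse-CDF sampling so a single uniform is
    consumed per parameter regardless of where the truncation falls.  Tc is
    reported as delta - ga_days so that the combined shift GA+Tc is centred
    near zero.
    """
    settings.validate()

    # amplitude: truncated normal
    a_lo = (settings.a_min - settings.a_mean) / settings.a_sd
    a_hi = (settings.a_max - settings.a_mean) / settings.a_sd
    a = float(
        stats.truncnorm.ppf(
            rng.uniform(), a_lo, a_hi, loc=settings.a_mean, scale=settings.a_sd
        )
    )

    # decay rate: log-normal matched to median + IQR, truncated above
    b_sigma = math.log(settings.b_q3 / settings.b_q1) / _IQR_TO_SIGMA
    b_dist = stats.lognorm(s=b_sigma, scale=settings.b_median)
    b_cap = float(b_dist.cdf(settings.b_max))
    b = float(b_dist.ppf(rng.uniform() * b_cap))

    # asymptote: zero-inflated truncated exponential
    if rng.uniform() < settings.c_zero_fraction:
        c = 0.0
    else:
        u = rng.uniform()
        mass = 1.0 - math.exp(-settings.c_trunc / settings.c_exp_mean)
        c = -settings.c_exp_mean * math.log1p(-u * mass)

    delta = float(rng.normal(0.0, settings.delta_sd_days))
    tc = delta - ga_days

    if settings.noise_sd_fixed is not None:
        noise_sd = float(settings.noise_sd_fixed)
    else:
        shape = (settings.noise_mean / settings.noise_sd) ** 2
        scale = settings.noise_sd**2 / settings.noise_mean
        noise_sd = float(rng.gamma(shape, scale))

    params = DecayParameters(a=a, b=b, c=c, tc=tc, ga_days=ga_days)
    return params, noise_sd


def _count_pmf(settings: GeneratorSettings) -> tuple[np.ndarray, np.ndarray]:
    """PMF of the samples-per-infant count: mass on {4,5,6} + geometric tail."""
    lo, hi = settings.n_samples_min, settings.n_samples_max
    values = np.arange(lo, hi + 1)
    probs = np.zeros(values.size)
    head = dict(zip((4, 5, 6), settings.count_pmf_456))
    for i, v in enumerate(values):
        probs[i] = head.get(int(v), 0.0)
    tail = values[values > 6]
    head_mass = probs.sum()
    if tail.size and head_mass < 1.0:
        w = settings.count_tail_ratio ** (tail - 7)
        probs[values > 6] = (1.0 - head_mass) * w / w.sum()
    if probs.sum() <= 0:
        raise ConfigurationError("count distribution has no support")
    return values, probs / probs.sum()


def generate_schedule(
    rng: np.random.Generator, settings: GeneratorSettings
) -> list[float]:
    """Draw a strictly increasing TSB sampling schedule (PNA, days).

    First draw is at or after 72 h of life; consecutive gaps are capped at
    ``schedule_max_gap_days`` so default cohorts pass the monitoring-gap
    filter (raise the cap to emit violators for filter tests).
    """
    settings.validate()
    if settings.n_fixed is not None:
        n = settings.n_fixed
    else:
        values, probs = _count_pmf(settings)
        n = int(rng.choice(values, p=probs))

    if settings.first_pna_fixed is not None:
        first = settings.first_pna_fixed
    else:
        sigma = math.log(settings.first_pna_q3 / settings.first_pna_q1) / _IQR_TO_SIGMA
        first = float(
            stats.lognorm.ppf(rng.uniform(), s=sigma, scale=settings.first_pna_median)
        )
        first = max(first, settings.first_pna_min)

    times = [first]
    for _ in range(n - 1):
        if settings.gap_fixed is not None:
            gap = settings.gap_fixed
        else:
            gap = float(
                stats.lognorm.ppf(
                    rng.uniform(), s=settings.gap_sigma, scale=settings.gap_median_days
                )
            )
            gap = min(max(gap, settings.gap_min_days), settings.schedule_max_gap_days)
        times.append(times[-1] + gap)
    return times


def simulate_trajectory(
    params: DecayParameters,
    schedule: list[float],
    noise_sd: float,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
    event: Optional[EventSpec] = None,
) -> tuple[list[TsbMeasurement], int]:
    """Evaluate the mean curve (+ optional event bump) and add noise.

    Negative simulated TSB is clipped to 0; the clip count is returned and
    logged so heavy clipping is visible in diagnostics.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    p = np.asarray(schedule, dtype=float)
    mean = eval_patient_specific(params, p)
    if event is not None:
        mean = mean + event.bump(p)
    noisy = mean + rng.normal(0.0, noise_sd, size=p.size) if noise_sd > 0 else mean
    n_clipped = int(np.sum(noisy < 0))
    if n_clipped:
        log.debug("patient %s: clipped %d negative TSB draws", patient_id, n_clipped)
    noisy = np.maximum(noisy, 0.0)
    return (
        [TsbMeasurement(patient_id, float(t), float(v)) for t, v in zip(p, noisy)],
        n_clipped,
    )


def inject_event(
    patient: PatientRecord,
    truth: PatientTruth,
    rng: np.random.Generator,
    settings: GeneratorSettings,
) -> tuple[PatientRecord, PatientTruth]:
    """Superimpose a morbidity episode on an already-simulated patient.

    Adds a Gaussian-shaped TSB rebound to the measurements (additive, so the
    realized noise is untouched) and appends one elevated CRP record within
    +/-2 days of the episode centre, clamped into the observed TSB span so
    the post-hoc CRP window always sees it.  If the drawn centre falls
    outside the schedule it is shifted to the covered range (with a warning).
    """
    amp = float(rng.uniform(*settings.event_amplitude_range))
    center = float(rng.uniform(*settings.event_center_range))
    width = float(rng.uniform(*settings.event_width_range))
    crp_value = float(rng.uniform(*settings.event_crp_range))
    crp_offset = float(rng.uniform(-2.0, 2.0))

    first, last = patient.measurements[0].pna_days, patient.measurements[-1].pna_days
    if not first <= center <= last:
        shifted = min(max(center, first), last)
        log.warning(
            "patient %s: event centre %.2f outside schedule [%.2f, %.2f]; "
            "shifted to %.2f",
            patient.patient_id, center, first, last, shifted,
        )
        center = shifted

    event = EventSpec(center_pna=center, amplitude=amp, width=width)
    bumped = [
        TsbMeasurement(
            m.patient_id, m.pna_days, float(m.tsb_umol_l + event.bump(m.pna_days))
        )
        for m in patient.measurements
    ]
    crp_pna = min(max(center + crp_offset, first), last)
    crp = sorted(
        list(patient.crp)
        + [CrpMeasurement(patient.patient_id, crp_pna, max(crp_value, 5.01))],
        key=lambda c: c.pna_days,
    )
    new_patient = replace(patient, measurements=bumped, crp=crp)
    new_truth = replace(
        truth,
        event_injected=True,
        event_center_pna=center,
        event_amplitude=amp,
        event_width=width,
    )
    return new_patient, new_truth


def generate_cohort(
    settings: GeneratorSettings,
) -> tuple[list[PatientRecord], SyntheticTruth]:
    """Generate a full cohort plus ground truth, reproducibly from the seed.

    Event and phototherapy assignment use exact counts
    (round(fraction * n)) drawn without replacement from a master stream;
    everything patient-specific comes from the (seed, index) substream.
    """
    settings.validate()
    n = settings.n_patients
    master = np.random.default_rng([settings.seed, 2**20])
    n_events = int(round(settings.event_fraction * n))
    n_pt = int(round(settings.pt_fraction * n))
    event_ids = set(master.choice(n, size=n_events, replace=False)) if n_events else set()
    pt_ids = set(master.choice(n, size=n_pt, replace=False)) if n_pt else set()

    cohort: list[PatientRecord] = []
    truth = SyntheticTruth(settings=settings)
    width = max(4, len(str(max(n - 1, 0))))
    for i in range(n):
        rng = _patient_rng(settings.seed, i)
        pid = f"S{i:0{width}d}"
        ga = float(rng.uniform(settings.ga_min_days, settings.ga_max_days))
        params, noise_sd = sample_patient_parameters(rng, settings, ga)
        schedule = generate_schedule(rng, settings)
        measurements, n_clipped = simulate_trajectory(
            params, schedule, noise_sd, rng, patient_id=pid
        )

        treatments = []
        if i in pt_ids:
            start = float(rng.uniform(*settings.pt_start_range))
            duration = float(rng.uniform(*settings.pt_duration_range))
            treatments.append(
                TreatmentInterval(pid, "phototherapy", start, start + duration)
            )

        crp = []
        n_crp = int(rng.integers(0, settings.baseline_crp_max_draws + 1))
        for _ in range(n_crp):
            crp.append(
                CrpMeasurement(
                    pid,
                    float(rng.uniform(schedule[0], schedule[-1])),
                    float(rng.uniform(*settings.baseline_crp_range)),
                )
            )
        crp.sort(key=lambda c: c.pna_days)

        patient = PatientRecord(
            patient_id=pid,
            ga_days=ga,
            measurements=measurements,
            treatments=treatments,
            crp=crp,
        )
        ptruth = PatientTruth(params=params, noise_sd=noise_sd, n_clipped=n_clipped)
        if i in event_ids:
            patient, ptruth = inject_event(patient, ptruth, rng, settings)
        cohort.append(patient)
        truth.patients[pid] = ptruth

    log.info(
        "generated cohort: %d patients, %d with events, %d with phototherapy",
        n, len(event_ids), len(pt_ids),
    )
    return cohort, truth


def truth_frame(truth: SyntheticTruth):
    """Flatten a SyntheticTruth into a DataFrame for truth.csv."""
    import pandas as pd

    rows = []
    for pid in sorted(truth.patients):
        t = truth.patients[pid]
        rows.append(
            {
                "patient_id": pid,
                "A": t.params.a,
                "B": t.params.b,
                "C": t.params.c,
                "Tc": t.params.tc,
                "ga_days": t.params.ga_days,
                "noise_sd": t.noise_sd,
                "event_injected": t.event_injected,
                "event_center_pna": t.event_center_pna,
                "event_amplitude": t.event_amplitude,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "A", "B", "C", "Tc", "ga_days", "noise_sd",
            "event_injected", "event_center_pna", "event_amplitude",
        ],
    )
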