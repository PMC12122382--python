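"""Cohort inclusion/exclusion cascade.

Selection of the modeled subgroup proceeds per patient, first failing rule
wins:

1. fewer than ``min_samples`` TSB measurements (default 4) -> excluded;
2. any pair of adjacent measurements more than ``max_gap_days`` apart
   (default 10, strict inequality) -> excluded as infrequently monitored;
3. samples drawn during phototherapy or exchange-transfusion intervals
   (closed intervals) are removed, and the minimum-sample rule is
   re-checked on what remains.

The gap rule is evaluated on the full record by default (infrequent
monitoring is a property of the observation record itself); set
``gap_check_stage="post_strip"`` to evaluate it after treatment-sample
removal instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import PatientRecord, TsbMeasurement
from .io import RunConfig

__all__ = [
    "FilterOutcome",
    "check_min_samples",
    "check_monitoring_gap",
    "strip_treatment_samples",
    "apply_inclusion_pipeline",
    "filter_report_frame",
    "included_patients",
]

log = logging.getLogger(__name__)

REASONS = (
    "too_few_samples",
    "infrequent_monitoring",
    "too_few_after_treatment_removal",
    "none",
)


@dataclass
class FilterOutcome:
    patient_id: str
    status: str  # "included" | "excluded"
    primary_reason: str
    retained_measurements: list[TsbMeasurement] = field(default_factory=list)
    removed_measurements: list[tuple[TsbMeasurement, str]] = field(default_factory=list)
    n_total: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("included", "excluded"):
            raise ValueError(f"bad status {self.status!r}")
        if self.primary_reason not in REASONS:
            raise ValueError(f"bad primary_reason {self.primary_reason!r}")
        if self.status == "included" and self.primary_reason != "none":
            raise ValueError("included patients carry no exclusion reason")


def check_min_samples(patient: PatientRecord, min_samples: int = 4) -> bool:
    """True iff the patient has at least ``min_samples`` measurements.

    'Fewer than 4' excludes only counts <= 3: exactly 4 passes.
    """
    return len(patient.measurements) >= min_samples


def check_monitoring_gap(patient: PatientRecord, max_gap_days: float = 10.0) -> bool:
    """True iff every consecutive PNA gap is <= ``max_gap_days``.

    Only strictly larger gaps fail ('more than 10 days apart'); requires at
    least two measurements, so apply the minimum-sample rule first.
    """
    pna = patient.pna
    if len(pna) < 2:
        raise ValueError(
            f"patient {patient.patient_id}: gap check needs >= 2 measurements"
        )
    return all(b - a <= max_gap_days for a, b in zip(pna, pna[1:]))


def strip_treatment_samples(
    patient: PatientRecord,
) -> tuple[list[TsbMeasurement], list[TsbMeasurement]]:
    """Split measurements into (retained, removed-during-treatment).

    A sample is removed iff some treatment interval covers it (closed
    interval: a draw at treatment cessation still reflects treatment
    effect); phototherapy and exchange transfusion count alike.
    """
    retained, removed = [], []
    for m in patient.measurements:
        if any(t.covers(m.pna_days) for t in patient.treatments):
            removed.append(m)
        else:
            retained.append(m)
    return retained, removed


def apply_inclusion_pipeline(
    cohort: list[PatientRecord], config: RunConfig | None = None
) -> list[FilterOutcome]:
    """Run the inclusion cascade over a cohort; one outcome per patient."""
    cfg = config or RunConfig()
    outcomes: list[FilterOutcome] = []
    for patient in cohort:
        n_total = len(patient.measurements)
        if not check_min_samples(patient, cfg.min_samples):
            outcomes.append(
                FilterOutcome(
                    patient.patient_id, "excluded", "too_few_samples",
                    retained_measurements=[],
                    removed_measurements=[(m, "excluded_patient")
                                          for m in patient.measurements],
                    n_total=n_total,
                )
            )
            continue

        retained, removed = strip_treatment_samples(patient)
        gap_basis = patient if cfg.gap_check_stage == "pre_strip" else (
            patient.with_measurements(retained) if len(retained) >= 2 else patient
        )
        if not check_monitoring_gap(gap_basis, cfg.max_gap_days):
            outcomes.append(
                FilterOutcome(
                    patient.patient_id, "excluded", "infrequent_monitoring",
                    retained_measurements=[],
                    removed_measurements=[(m, "excluded_patient")
                                          for m in patient.measurements],
                    n_total=n_total,
                )
            )
            continue

        if len(retained) < cfg.min_samples:
            outcomes.append(
                FilterOutcome(
                    patient.patient_id, "excluded",
                    "too_few_after_treatment_removal",
                    retained_measurements=[],
                    removed_measurements=(
                        [(m, "during_treatment") for m in removed]
                        + [(m, "excluded_patient") for m in retained]
                    ),
                    n_total=n_total,
                )
            )
            continue

        outcomes.append(
            FilterOutcome(
                patient.patient_id, "included", "none",
                retained_measurements=retained,
                removed_measurements=[(m, "during_treatment") for m in removed],
                n_total=n_total,
            )
        )

    counts = Counter(o.primary_reason for o in outcomes if o.status == "excluded")
    log.info(
        "inclusion pipeline: %d/%d included; exclusions: %s",
        sum(o.status == "included" for o in outcomes), len(outcomes), dict(counts),
    )
    return outcomes


def included_patients(
    cohort: list[PatientRecord], outcomes: list[FilterOutcome]
) -> list[PatientRecord]:
    """Included patients with their retained measurement lists applied."""
    by_id = {o.patient_id: o for o in outcomes}
    result = []
    for patient in cohort:
        o = by_id[patient.patient_id]
        if o.status == "included":
            result.append(patient.with_measurements(o.retained_measurements))
    return result


def filter_report_frame(outcomes: list[FilterOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "status": o.status,
                "primary_reason": o.primary_reason,
                "n_total": o.n_total,
                "n_retained": len(o.retained_measurements),
            }
            for o in sorted(outcomes, key=lambda o: o.patient_id)
        ],
        columns=["patient_id", "status", "primary_reason", "n_total", "n_retained"],
    )
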