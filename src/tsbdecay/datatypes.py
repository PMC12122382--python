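"""Core clinical data model.

Total serum bilirubin (TSB) follow-up in very preterm infants is recorded as
sparse longitudinal series: per infant, a handful of (postnatal age, TSB)
pairs, together with gestational age at birth, treatment intervals
(phototherapy / exchange transfusion), C-reactive protein (CRP) measurements
and outcome events.  All times are postnatal age (PNA) in days with 0 at
birth; gestational age is stored in days (weeks x 7 + days) so that model
time shifts live on a single axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "TsbMeasurement",
    "TreatmentInterval",
    "CrpMeasurement",
    "OutcomeEvent",
    "PatientRecord",
    "GA_DAYS_MIN",
    "GA_DAYS_MAX",
]

#: Default gestational-age validation window: 24 to <32 completed weeks.
GA_DAYS_MIN = 168.0
GA_DAYS_MAX = 224.0

TREATMENT_KINDS = ("phototherapy", "exchange_transfusion")

#: CSV abbreviations used on disk (PT/ET) mapped to canonical kinds.
TREATMENT_ALIASES = {
    "PT": "phototherapy",
    "ET": "exchange_transfusion",
    "phototherapy": "phototherapy",
    "exchange_transfusion": "exchange_transfusion",
}


@dataclass(frozen=True)
class TsbMeasurement:
    """One (patient, PNA, TSB) observation."""

    patient_id: str
    pna_days: float
    tsb_umol_l: float

    def __post_init__(self) -> None:
        if self.pna_days < 0:
            raise ValueError(f"pna_days must be >= 0, got {self.pna_days}")
        if self.tsb_umol_l < 0:
            raise ValueError(f"tsb_umol_l must be >= 0, got {self.tsb_umol_l}")


@dataclass(frozen=True)
class TreatmentInterval:
    """A phototherapy or exchange-transfusion interval, [start, end] in PNA days."""

    patient_id: str
    kind: str
    start_pna_days: float
    end_pna_days: float

    def __post_init__(self) -> None:
        if self.kind not in TREATMENT_KINDS:
            raise ValueError(
                f"kind must be one of {TREATMENT_KINDS}, got {self.kind!r}"
            )
        if not 0 <= self.start_pna_days <= self.end_pna_days:
            raise ValueError(
                "treatment interval requires 0 <= start <= end, got "
                f"[{self.start_pna_days}, {self.end_pna_days}]"
            )

    def covers(self, pna_days: float) -> bool:
        """Closed-interval membership: a sample drawn at treatment cessation
        still reflects treatment effect."""
        return self.start_pna_days <= pna_days <= self.end_pna_days


@dataclass(frozen=True)
class CrpMeasurement:
    """One C-reactive protein observation, mg/L."""

    patient_id: str
    pna_days: float
    crp_mg_l: float

    def __post_init__(self) -> None:
        if self.pna_days < 0:
            raise ValueError(f"pna_days must be >= 0, got {self.pna_days}")
        if self.crp_mg_l < 0:
            raise ValueError(f"crp_mg_l must be >= 0, got {self.crp_mg_l}")


@dataclass(frozen=True)
class OutcomeEvent:
    """A labelled clinical outcome (e.g. NEC, death) with its PNA."""

    patient_id: str
    event: str
    pna_days: float


@dataclass
class PatientRecord:
    """One infant: GA at birth plus all longitudinal child records.

    ``measurements`` is kept sorted by ``pna_days``; ties are preserved in
    input order (Python's sort is stable).
    """

    patient_id: str
    ga_days: float
    birth_weight_g: Optional[float] = None
    sex: Optional[str] = None
    measurements: list[TsbMeasurement] = field(default_factory=list)
    treatments: list[TreatmentInterval] = field(default_factory=list)
    crp: list[CrpMeasurement] = field(default_factory=list)
    outcomes: list[OutcomeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort_measurements()

    def sort_measurements(self) -> None:
        self.measurements.sort(key=lambda m: m.pna_days)

    def validate_ga(self, lo: float = GA_DAYS_MIN, hi: float = GA_DAYS_MAX) -> None:
        if not lo <= self.ga_days < hi:
            raise ValueError(
                f"patient {self.patient_id}: ga_days={self.ga_days} outside "
                f"[{lo}, {hi})"
            )
        for child in (self.measurements, self.treatments, self.crp, self.outcomes):
            for rec in child:
                if rec.patient_id != self.patient_id:
                    raise ValueError(
                        f"child record {rec} does not belong to patient "
                        f"{self.patient_id}"
                    )

    @property
    def pna(self) -> list[float]:
        return [m.pna_days for m in self.measurements]

    @property
    def tsb(self) -> list[float]:
        return [m.tsb_umol_l for m in self.measurements]

    def with_measurements(self, measurements: list[TsbMeasurement]) -> "PatientRecord":
        """Copy of this record with a replacement measurement list."""
        return replace(self, measurements=list(measurements))


def ga_weeks_to_days(weeks: float, extra_days: float = 0.0) -> float:
    """Convert clinical 'weeks + days' gestational age to days."""
    return weeks * 7.0 + extra_days
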