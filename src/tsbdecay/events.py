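"""Model misfit versus clinical events.

High RMSE of a patient-specific decay fit flags trajectories the natural
decay cannot explain — rebounds coinciding with morbidity such as NEC or
infection.  This module quantifies that association on a cohort (elevated
CRP counts within the post-phototherapy observation window, RMSE-sorted
association table with a rank correlation) and provides a per-measurement
deviation alert: a newly observed TSB further than
max(k_sigma * RMSE, abs_floor) from the fitted curve raises a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PatientRecord, TsbMeasurement
from .fitting import FitResult
from .models import eval_patient_specific

__all__ = [
    "CrpWindowStats",
    "crp_window",
    "rmse_crp_table",
    "DeviationAlert",
    "deviation_alert",
]

log = logging.getLogger(__name__)


@dataclass
class CrpWindowStats:
    patient_id: str
    window_start_pna: float
    window_end_pna: float
    n_elevated: int
    max_crp: float  # max CRP inside the window, 0 if none


def crp_window(patient: PatientRecord, threshold_mg_l: float = 5.0) -> CrpWindowStats:
    """Count elevated CRP results in the patient's observation window.

    Phototherapy recipients: window is (end of last phototherapy interval,
    PNA of last TSB measurement] — start exclusive, end inclusive.  Patients
    without phototherapy: the full TSB span [first, last], both inclusive.
    'Elevated' is strictly greater than the threshold (default 5 mg/L).
    """
    if not patient.measurements:
        raise ValueError(f"patient {patient.patient_id} has no TSB measurements")
    last_tsb = patient.measurements[-1].pna_days
    pt_ends = [
        t.end_pna_days for t in patient.treatments if t.kind == "phototherapy"
    ]
    if pt_ends:
        start, start_inclusive = max(pt_ends), False
    else:
        start, start_inclusive = patient.measurements[0].pna_days, True

    def in_window(pna: float) -> bool:
        after_start = pna >= start if start_inclusive else pna > start
        return after_start and pna <= last_tsb

    inside = [c.crp_mg_l for c in patient.crp if in_window(c.pna_days)]
    elevated = [v for v in inside if v > threshold_mg_l]
    return CrpWindowStats(
        patient_id=patient.patient_id,
        window_start_pna=start,
        window_end_pna=last_tsb,
        n_elevated=len(elevated),
        max_crp=max(inside, default=0.0),
    )


def rmse_crp_table(
    fits: list[FitResult],
    cohort: list[PatientRecord],
    threshold_mg_l: float = 5.0,
) -> tuple[pd.DataFrame, float | None]:
    """Per-patient (RMSE, elevated-CRP count, max CRP) table, RMSE-ascending.

    Returns the table together with the Spearman rank correlation between
    RMSE and the elevated-CRP count, or ``None`` when the correlation is
    undefined (no variation in one of the columns).
    """
    by_id = {p.patient_id: p for p in cohort}
    missing = sorted(f.patient_id for f in fits if f.patient_id not in by_id)
    if missing:
        raise ValueError(f"fits reference patients absent from cohort: {missing}")
    rows = []
    for f in fits:
        w = crp_window(by_id[f.patient_id], threshold_mg_l)
        rows.append(
            {
                "patient_id": f.patient_id,
                "rmse": f.rmse,
                "n_elevated": w.n_elevated,
                "max_crp": w.max_crp,
            }
        )
    table = (
        pd.DataFrame(rows, columns=["patient_id", "rmse", "n_elevated", "max_crp"])
        .sort_values(["rmse", "patient_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    if len(table) < 2 or table["n_elevated"].nunique() < 2 or table["rmse"].nunique() < 2:
        log.info("Spearman(rmse, n_elevated) not applicable (degenerate column)")
        return table, None
    rho = float(stats.spearmanr(table["rmse"], table["n_elevated"]).statistic)
    return table, rho


@dataclass
class DeviationAlert:
    patient_id: str
    pna_days: float
    observed_tsb: float
    predicted_tsb: float
    residual: float
    threshold_used: float
    alert: bool


def deviation_alert(
    fit: FitResult,
    new_measurement: TsbMeasurement,
    k_sigma: float = 2.0,
    abs_floor: float = 10.0,
) -> DeviationAlert:
    """Flag a new TSB measurement that deviates from the fitted decay.

    The alert threshold is max(k_sigma * fit RMSE, abs_floor µmol/L); the
    floor keeps near-perfect fits from alerting on clinically negligible
    deviations.
    """
    if not fit.converged:
        raise ValueError(
            f"fit for patient {fit.patient_id} did not converge; refit before "
            "using deviation alerts"
        )
    predicted = float(eval_patient_specific(fit.params, new_measurement.pna_days))
    residual = new_measurement.tsb_umol_l - predicted
    threshold = max(k_sigma * fit.rmse, abs_floor)
    return DeviationAlert(
        patient_id=fit.patient_id,
        pna_days=new_measurement.pna_days,
        observed_tsb=new_measurement.tsb_umol_l,
        predicted_tsb=predicted,
        residual=float(residual),
        threshold_used=float(threshold),
        alert=bool(abs(residual) > threshold),
    )
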