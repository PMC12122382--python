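"""CSV input/output and run configuration.

All tabular interchange is plain CSV (comma-separated, UTF-8, header row,
'.' decimal separator):

* ``measurements.csv``: patient_id,pna_days,tsb_umol_l
* ``patients.csv``:     patient_id,ga_days,birth_weight_g,sex
  (``ga_weeks`` [+ optional ``ga_plus_days``] is accepted in place of
  ``ga_days`` and converted as weeks*7 + days)
* ``treatments.csv``:   patient_id,kind,start_pna_days,end_pna_days
  (kind in {PT, ET} or the long names)
* ``crp.csv``:          patient_id,pna_days,crp_mg_l
* ``events.csv``:       patient_id,event,pna_days

Treatments, CRP and events files are optional; missing ones yield empty
lists.  The run configuration is a flat ``key: value`` text file (a YAML
mapping); unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .datatypes import (
    GA_DAYS_MAX,
    GA_DAYS_MIN,
    TREATMENT_ALIASES,
    CrpMeasurement,
    OutcomeEvent,
    PatientRecord,
    TreatmentInterval,
    TsbMeasurement,
)

__all__ = [
    "CohortIOError",
    "SchemaError",
    "RowValidationError",
    "ReferentialError",
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_cohort",
    "write_cohort",
]

log = logging.getLogger(__name__)


class CohortIOError(Exception):
    """Base class for cohort I/O failures."""


class SchemaError(CohortIOError):
    """A required column is missing."""


class RowValidationError(CohortIOError):
    """A row holds a non-numeric or out-of-range value; cites the line."""


class ReferentialError(CohortIOError):
    """Child rows reference a patient_id absent from patients.csv."""


class ConfigError(Exception):
    """Bad run-configuration file."""


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Time is in days, TSB in µmol/L, CRP in mg/L throughout.
    """

    # --- cohort filters -------------------------------------------------
    min_samples: int = 4              # exclude infants with fewer TSB draws
    max_gap_days: float = 10.0        # exclude if adjacent draws > this apart
    gap_check_stage: str = "pre_strip"  # {"pre_strip", "post_strip"}

    # --- patient-specific fitting --------------------------------------
    a_max: float = 200.0              # amplitude bound
    b_max: float = 1.5                # decay-rate bound, 1/day
    c_max: float = 500.0              # finite stand-in for C in [0, +inf)
    delta_halfwidth_days: float = 100.0  # GA+Tc searched in +/- this window
    b_starts: list = field(default_factory=lambda: [0.05, 0.11, 0.3])
    delta_starts: list = field(default_factory=lambda: [0.0, -20.0, 20.0])
    loss_scales: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    fit_tol: float = 1e-10            # ftol = xtol = gtol of the NLS solver
    max_nfev: int = 2000              # per candidate configuration

    # --- synthetic cohort ----------------------------------------------
    n_patients: int = 72
    seed: int = 0
    ga_min_days: float = GA_DAYS_MIN
    ga_max_days: float = GA_DAYS_MAX
    a_mean: float = 120.9
    a_sd: float = 27.54
    b_median: float = 0.11
    b_q1: float = 0.06
    b_q3: float = 0.21
    c_zero_fraction: float = 0.75
    c_exp_mean: float = 35.0
    c_trunc: float = 175.0
    delta_sd_days: float = 10.0
    noise_mean: float = 10.62
    noise_sd: float = 7.69
    first_pna_median: float = 4.3
    first_pna_q1: float = 2.0
    first_pna_q3: float = 7.0
    first_pna_min: float = 3.0
    gap_median_days: float = 2.0
    gap_sigma: float = 0.6
    gap_min_days: float = 0.25
    schedule_max_gap_days: float = 10.0
    n_samples_min: int = 4
    n_samples_max: int = 20
    event_fraction: float = 1.0 / 6.0
    event_amplitude_range: list = field(default_factory=lambda: [40.0, 120.0])
    event_center_range: list = field(default_factory=lambda: [10.0, 30.0])
    event_width_range: list = field(default_factory=lambda: [1.5, 4.0])
    event_crp_range: list = field(default_factory=lambda: [20.0, 300.0])
    pt_fraction: float = 0.15
    write_empty_optional_files: bool = True

    # --- population analysis -------------------------------------------
    sweep_n_grid: int = 9
    pna_grid_max: float = 60.0
    pna_grid_step: float = 0.25
    alpha: float = 0.05
    n_comparisons: int = 20

    # --- event association ---------------------------------------------
    crp_threshold_mg_l: float = 5.0
    alert_k_sigma: float = 2.0
    alert_abs_floor: float = 10.0


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a flat key:value config file; absent path means all defaults.

    Unknown keys raise :class:`ConfigError` listing the valid keys; values
    of the wrong type raise too (ints are accepted where floats are
    expected).
    """
    cfg = RunConfig()
    if path is None:
        log.info("config: all defaults")
        return cfg
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a flat key: value mapping")
    for key, value in raw.items():
        if key not in _CONFIG_FIELDS:
            raise ConfigError(
                f"unknown config key {key!r}; valid keys: "
                + ", ".join(sorted(_CONFIG_FIELDS))
            )
        current = getattr(cfg, key)
        if isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"config key {key!r} expects a boolean")
        elif isinstance(current, int):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"config key {key!r} expects an integer")
        elif isinstance(current, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"config key {key!r} expects a number")
            value = float(value)
        elif isinstance(current, list):
            if not isinstance(value, list):
                raise ConfigError(f"config key {key!r} expects a list")
            value = [float(v) for v in value]
        elif isinstance(current, str):
            if not isinstance(value, str):
                raise ConfigError(f"config key {key!r} expects a string")
        setattr(cfg, key, value)
    log.info("config: %s", cfg)
    return cfg


# ---------------------------------------------------------------------------
# reading


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column {col!r}")


def _numeric_column(
    df: pd.DataFrame, col: str, name: str, minimum: Optional[float] = None
) -> pd.Series:
    """Coerce a column to float, reporting the 1-based file line of failures."""
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if df[col].isna().any():
        bad |= df[col].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RowValidationError(
            f"{name} line {line}: non-numeric value {df[col][bad.idxmax()]!r} "
            f"in column {col!r}"
        )
    if minimum is not None and (values < minimum).any():
        idx = int((values < minimum).idxmax())
        raise RowValidationError(
            f"{name} line {idx + 2}: value {values[idx]} in column {col!r} "
            f"below minimum {minimum}"
        )
    return values.astype(float)


def _read_csv(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"{name}: file not found: {path}")
    # round_trip parsing keeps read(write(x)) bit-identical for floats
    return pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")


def read_cohort(
    measurements_path: str | Path,
    patients_path: str | Path,
    treatments_path: Optional[str | Path] = None,
    crp_path: Optional[str | Path] = None,
    events_path: Optional[str | Path] = None,
    validate_ga: bool = True,
) -> list[PatientRecord]:
    """Read CSV files into one :class:`PatientRecord` per patients-file row.

    Measurements end up sorted by PNA within each patient.  Child rows whose
    ``patient_id`` is absent from the patients file are a referential error.
    Optional paths may be ``None`` (or point to header-only files).
    """
    pat_df = _read_csv(patients_path, "patients")
    _require_columns(pat_df, ["patient_id"], "patients")
    if "ga_days" in pat_df.columns:
        ga = _numeric_column(pat_df, "ga_days", "patients", minimum=0.0)
    elif "ga_weeks" in pat_df.columns:
        weeks = _numeric_column(pat_df, "ga_weeks", "patients", minimum=0.0)
        if "ga_plus_days" in pat_df.columns:
            plus = _numeric_column(pat_df, "ga_plus_days", "patients", minimum=0.0)
        else:
            plus = pd.Series(0.0, index=pat_df.index)
        ga = weeks * 7.0 + plus
    else:
        raise SchemaError("patients: missing required column 'ga_days' (or 'ga_weeks')")

    records: dict[str, PatientRecord] = {}
    for idx, row in pat_df.iterrows():
        pid = str(row["patient_id"])
        if pid in records:
            raise RowValidationError(
                f"patients line {int(idx) + 2}: duplicate patient_id {pid!r}"
            )
        bw = row.get("birth_weight_g")
        sex = row.get("sex")
        records[pid] = PatientRecord(
            patient_id=pid,
            ga_days=float(ga[idx]),
            birth_weight_g=None if pd.isna(bw) else float(bw),
            sex=None if (sex is None or pd.isna(sex)) else str(sex),
        )

    def _check_orphans(df: pd.DataFrame, name: str) -> None:
        orphan = sorted(set(df["patient_id"].astype(str)) - set(records))
        if orphan:
            raise ReferentialError(
                f"{name}: rows reference patient_id(s) absent from patients "
                f"file: {orphan}"
            )

    meas_df = _read_csv(measurements_path, "measurements")
    _require_columns(meas_df, ["patient_id", "pna_days", "tsb_umol_l"], "measurements")
    pna = _numeric_column(meas_df, "pna_days", "measurements", minimum=0.0)
    tsb = _numeric_column(meas_df, "tsb_umol_l", "measurements", minimum=0.0)
    _check_orphans(meas_df, "measurements")
    for idx, row in meas_df.iterrows():
        pid = str(row["patient_id"])
        records[pid].measurements.append(
            TsbMeasurement(pid, float(pna[idx]), float(tsb[idx]))
        )

    if treatments_path is not None and Path(treatments_path).exists():
        trt_df = _read_csv(treatments_path, "treatments")
        _require_columns(
            trt_df, ["patient_id", "kind", "start_pna_days", "end_pna_days"], "treatments"
        )
        start = _numeric_column(trt_df, "start_pna_days", "treatments", minimum=0.0)
        end = _numeric_column(trt_df, "end_pna_days", "treatments", minimum=0.0)
        _check_orphans(trt_df, "treatments")
        for idx, row in trt_df.iterrows():
            pid = str(row["patient_id"])
            kind = TREATMENT_ALIASES.get(str(row["kind"]))
            if kind is None:
                raise RowValidationError(
                    f"treatments line {int(idx) + 2}: unknown kind {row['kind']!r}"
                )
            records[pid].treatments.append(
                TreatmentInterval(pid, kind, float(start[idx]), float(end[idx]))
            )

    if crp_path is not None and Path(crp_path).exists():
        crp_df = _read_csv(crp_path, "crp")
        _require_columns(crp_df, ["patient_id", "pna_days", "crp_mg_l"], "crp")
        cpna = _numeric_column(crp_df, "pna_days", "crp", minimum=0.0)
        cval = _numeric_column(crp_df, "crp_mg_l", "crp", minimum=0.0)
        _check_orphans(crp_df, "crp")
        for idx, row in crp_df.iterrows():
            pid = str(row["patient_id"])
            records[pid].crp.append(CrpMeasurement(pid, float(cpna[idx]), float(cval[idx])))

    if events_path is not None and Path(events_path).exists():
        ev_df = _read_csv(events_path, "events")
        _require_columns(ev_df, ["patient_id", "event", "pna_days"], "events")
        epna = _numeric_column(ev_df, "pna_days", "events", minimum=0.0)
        _check_orphans(ev_df, "events")
        for idx, row in ev_df.iterrows():
            pid = str(row["patient_id"])
            records[pid].outcomes.append(
                OutcomeEvent(pid, str(row["event"]), float(epna[idx]))
            )

    cohort = [records[pid] for pid in records]
    for rec in cohort:
        rec.sort_measurements()
        if validate_ga:
            rec.validate_ga(GA_DAYS_MIN, GA_DAYS_MAX)
    log.info("read_cohort: %d patients, %d measurements",
             len(cohort), sum(len(r.measurements) for r in cohort))
    return cohort


# ---------------------------------------------------------------------------
# writing


def write_cohort(
    cohort: list[PatientRecord],
    out_dir: str | Path,
    write_empty_optional_files: bool = True,
) -> dict[str, Path]:
    """Write a cohort back to the CSV schemas :func:`read_cohort` accepts.

    Row order is deterministic (patient_id, then pna_days).  When
    ``write_empty_optional_files`` is false, optional files with no rows are
    omitted rather than written header-only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(cohort, key=lambda r: r.patient_id)

    kind_abbrev = {"phototherapy": "PT", "exchange_transfusion": "ET"}
    frames = {
        "patients": pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "ga_days": r.ga_days,
                    "birth_weight_g": r.birth_weight_g,
                    "sex": r.sex,
                }
                for r in ordered
            ],
            columns=["patient_id", "ga_days", "birth_weight_g", "sex"],
        ),
        "measurements": pd.DataFrame(
            [
                {"patient_id": r.patient_id, "pna_days": m.pna_days,
                 "tsb_umol_l": m.tsb_umol_l}
                for r in ordered
                for m in r.measurements
            ],
            columns=["patient_id", "pna_days", "tsb_umol_l"],
        ),
        "treatments": pd.DataFrame(
            [
                {"patient_id": r.patient_id, "kind": kind_abbrev[t.kind],
                 "start_pna_days": t.start_pna_days, "end_pna_days": t.end_pna_days}
                for r in ordered
                for t in sorted(r.treatments, key=lambda t: t.start_pna_days)
            ],
            columns=["patient_id", "kind", "start_pna_days", "end_pna_days"],
        ),
        "crp": pd.DataFrame(
            [
                {"patient_id": r.patient_id, "pna_days": c.pna_days,
                 "crp_mg_l": c.crp_mg_l}
                for r in ordered
                for c in sorted(r.crp, key=lambda c: c.pna_days)
            ],
            columns=["patient_id", "pna_days", "crp_mg_l"],
        ),
        "events": pd.DataFrame(
            [
                {"patient_id": r.patient_id, "event": e.event, "pna_days": e.pna_days}
                for r in ordered
                for e in sorted(r.outcomes, key=lambda e: e.pna_days)
            ],
            columns=["patient_id", "event", "pna_days"],
        ),
    }

    written: dict[str, Path] = {}
    for name, df in frames.items():
        optional = name in ("treatments", "crp", "events")
        if optional and df.empty and not write_empty_optional_files:
            continue
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    log.info("write_cohort: wrote %s to %s", sorted(written), out_dir)
    return written
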