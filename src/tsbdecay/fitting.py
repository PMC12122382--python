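"""Model fitting.

Three fits are provided:

* :func:`fit_linear_population` — ordinary least squares for the population
  linear trend;
* :func:`fit_exponential_population` — multi-start bounded nonlinear least
  squares for the population exponential decay;
* :func:`fit_patient` — the patient-specific fit: bounded robust nonlinear
  least squares on (A, B, C, Tc) with a deterministic multi-start grid and
  an adaptive robustness strategy.

The adaptive strategy runs a grid of candidate configurations: plain
least-squares from every start point, then a smooth-L1 ("soft-L1") robust
loss — rho(z) = 2(sqrt(1+z) - 1), a smooth approximation to absolute-error
regression — at scale factors {0.5, 1, 2, 4} x MAD of the residuals of the
best plain fit, warm-started from the deduplicated plain-fit solutions
(the converged minima already cover the basins the raw start grid was
designed to reach).  Whatever the loss used during
optimization, candidates are compared on their plain (unweighted) sum of
squared residuals and the lowest wins; ties break on the fixed enumeration
order (loss family, scale, start index), so the whole procedure is
deterministic.

Internally the time shift is optimized as delta = GA + Tc (order of days)
rather than raw Tc (order of -200 days) for conditioning; reported
parameters are (A, B, C, Tc) plus the identifiable composite set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import PatientRecord
from .io import RunConfig
from .models import (
    CompositeParameters,
    DecayParameters,
    GeneralExpParams,
    LinearParams,
    to_composite,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "fit_linear_population",
    "fit_exponential_population",
    "fit_patient",
    "fit_cohort",
    "fits_frame",
]

log = logging.getLogger(__name__)


@dataclass
class FitSettings:
    """Bounds, start grid and robustness grid for the patient-specific fit."""

    a_max: float = 200.0
    b_max: float = 1.5
    c_max: float = 500.0          # finite stand-in for C in [0, +inf)
    delta_halfwidth: float = 100.0  # GA+Tc searched in [-hw, +hw] days
    a_start_fallback: float = 120.0
    b_starts: Sequence[float] = (0.05, 0.11, 0.3)
    delta_starts: Sequence[float] = (0.0, -20.0, 20.0)
    loss_families: Sequence[str] = ("linear", "soft_l1")
    loss_scales: Sequence[float] = (0.5, 1.0, 2.0, 4.0)
    n_warm_starts: int = 6    # robust-phase warm starts kept after dedup
    tol: float = 1e-10
    max_nfev: int = 2000
    seed: int = 0

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "FitSettings":
        return cls(
            a_max=cfg.a_max,
            b_max=cfg.b_max,
            c_max=cfg.c_max,
            delta_halfwidth=cfg.delta_halfwidth_days,
            b_starts=tuple(cfg.b_starts),
            delta_starts=tuple(cfg.delta_starts),
            loss_scales=tuple(cfg.loss_scales),
            tol=cfg.fit_tol,
            max_nfev=cfg.max_nfev,
            seed=cfg.seed,
        )


@dataclass
class FitResult:
    """Outcome of one fit: parameters, residuals, misfit, provenance."""

    patient_id: str
    params: object  # DecayParameters | GeneralExpParams | LinearParams
    composite: Optional[CompositeParameters]
    residuals: np.ndarray
    rmse: float
    ssr: float
    n_samples: int
    converged: bool
    loss_config_used: str
    seed: int = 0
    ga_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_samples != len(self.residuals):
            raise ValueError("residuals length must equal n_samples")
        expected = float(np.sqrt(self.ssr / self.n_samples))
        if not np.isclose(self.rmse, expected, rtol=1e-9, atol=1e-12):
            raise ValueError("rmse must equal sqrt(ssr / n_samples)")


# ---------------------------------------------------------------------------
# population fits


def fit_linear_population(samples: list) -> FitResult:
    """Closed-form OLS of TSB on PNA over pooled samples."""
    t = np.array([m.pna_days for m in samples], dtype=float)
    y = np.array([m.tsb_umol_l for m in samples], dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("linear fit needs >= 2 samples with >= 2 distinct PNAs")
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    resid = y - pred
    ssr = float(resid @ resid)
    return FitResult(
        patient_id="population",
        params=LinearParams(intercept_a=float(coef[0]), slope_b=float(coef[1])),
        composite=None,
        residuals=resid,
        rmse=float(np.sqrt(ssr / t.size)),
        ssr=ssr,
        n_samples=int(t.size),
        converged=True,
        loss_config_used="ols",
    )


def fit_exponential_population(
    samples: list, settings: Optional[FitSettings] = None
) -> FitResult:
    """Multi-start NLS for ``A exp(-B t) + C`` with B >= 0.

    The decay constraint B >= 0 is the only bound the model statement
    imposes; A and C are left free.
    """
    settings = settings or FitSettings()
    t = np.array([m.pna_days for m in samples], dtype=float)
    y = np.array([m.tsb_umol_l for m in samples], dtype=float)
    if t.size < 4:
        raise ValueError("exponential fit needs >= 4 samples")

    def resid(x):
        return x[0] * np.exp(-x[1] * t) + x[2] - y

    def jac(x):
        e = np.exp(-x[1] * t)
        return np.column_stack([e, -x[0] * t * e, np.ones_like(t)])

    spread = float(y.max() - y.min())
    starts = [
        (spread if spread > 0 else 1.0, b0, float(y.min()))
        for b0 in settings.b_starts
    ] + [(float(y.mean()), 0.01, 0.0)]
    lo = [-np.inf, 0.0, -np.inf]
    hi = [np.inf, np.inf, np.inf]

    best = None
    converged = False
    for i, x0 in enumerate(starts):
        try:
            res = least_squares(
                resid, np.clip(x0, lo, hi), jac=jac, bounds=(lo, hi),
                method="trf", ftol=settings.tol, xtol=settings.tol,
                gtol=settings.tol, max_nfev=settings.max_nfev,
            )
        except Exception:  # singular start; other starts may still work
            continue
        r = resid(res.x)
        ssr = float(r @ r)
        converged = converged or res.status > 0
        if best is None or ssr < best[0]:
            best = (ssr, res.x, r, f"linear|start{i:02d}")
    if best is None:
        raise RuntimeError("exponential population fit failed from every start")
    ssr, x, r, label = best
    return FitResult(
        patient_id="population",
        params=GeneralExpParams(a=float(x[0]), b=float(x[1]), c=float(x[2])),
        composite=None,
        residuals=r,
        rmse=float(np.sqrt(ssr / t.size)),
        ssr=ssr,
        n_samples=int(t.size),
        converged=converged,
        loss_config_used=label,
    )


# ---------------------------------------------------------------------------
# patient-specific fit


def _starts(y: np.ndarray, settings: FitSettings) -> list[tuple]:
    """Deterministic multi-start grid in (A, B, C, delta) space."""
    a_starts = [min(float(y.max()), settings.a_max), settings.a_start_fallback]
    c_starts = [0.0, float(y.min())]
    return [
        (a0, b0, c0, d0)
        for a0, b0, c0, d0 in product(
            a_starts, settings.b_starts, c_starts, settings.delta_starts
        )
    ]


def fit_patient(
    patient: PatientRecord, settings: Optional[FitSettings] = None
) -> FitResult:
    """Fit the patient-specific decay curve to one infant's retained samples.

    Requires at least 4 measurements (fewer signals a filtering bug
    upstream).  Returns the candidate with the lowest plain SSR; if no
    candidate converges the best-effort parameters are returned with
    ``converged=False``.
    """
    settings = settings or FitSettings()
    if len(patient.measurements) < 4:
        raise ValueError(
            f"patient {patient.patient_id}: fit needs >= 4 retained "
            f"measurements, got {len(patient.measurements)}"
        )
    p = np.array(patient.pna, dtype=float)
    y = np.array(patient.tsb, dtype=float)
    ga = float(patient.ga_days)

    # x = (A, B, C, delta) with delta = GA + Tc
    def resid(x):
        return x[0] * np.exp(-x[1] * (p + x[3])) + x[2] - y

    def jac(x):
        e = np.exp(-x[1] * (p + x[3]))
        return np.column_stack(
            [e, -x[0] * (p + x[3]) * e, np.ones_like(p), -x[0] * x[1] * e]
        )

    lo = np.array([0.0, 0.0, 0.0, -settings.delta_halfwidth])
    hi = np.array([settings.a_max, settings.b_max, settings.c_max,
                   settings.delta_halfwidth])
    x_scale = np.array([100.0, 0.1, 100.0, 10.0])
    starts = _starts(y, settings)

    def run(x0, loss, f_scale, label):
        try:
            res = least_squares(
                resid, np.clip(x0, lo, hi), jac=jac, bounds=(lo, hi),
                method="trf", loss=loss, f_scale=f_scale, x_scale=x_scale,
                ftol=settings.tol, xtol=settings.tol, gtol=settings.tol,
                max_nfev=settings.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.debug("candidate %s failed: %s", label, exc)
            return None
        r = resid(res.x)
        return (float(r @ r), res.x, r, res.status > 0, label)

    # The plain phase always runs: it supplies the robust phase's residual
    # scale (MAD) and warm starts.  Its candidates only compete for
    # selection when "linear" is among the enabled loss families.
    plain = []
    for i, x0 in enumerate(starts):
        out = run(x0, "linear", 1.0, f"linear|start{i:02d}")
        if out is not None:
            plain.append(out)
    candidates = list(plain) if "linear" in settings.loss_families else []
    # Robust phase warm-starts: the plain solutions, deduplicated in scaled
    # parameter space and ordered by SSR, capped at n_warm.  Warm-starting
    # from converged plain minima covers the same basins as the raw start
    # grid at a fraction of the solver calls.
    warm: list[np.ndarray] = []
    seen = set()
    for ssr_c, x_c, *_ in sorted(plain, key=lambda c: c[0]):
        key = tuple(np.round(x_c / x_scale, 3))
        if key not in seen:
            seen.add(key)
            warm.append(x_c)
        if len(warm) >= settings.n_warm_starts:
            break
    if plain:
        r0 = min(plain, key=lambda c: c[0])[2]
        mad = float(np.median(np.abs(r0 - np.median(r0))))
    else:
        mad, warm = 0.0, [np.asarray(s) for s in starts]
    scale_floor = 1e-6  # soft-L1 needs a strictly positive scale
    if "soft_l1" in settings.loss_families:
        for factor in settings.loss_scales:
            f_scale = max(factor * mad, scale_floor)
            for j, x0 in enumerate(warm):
                out = run(x0, "soft_l1", f_scale, f"soft_l1|x{factor:g}|warm{j:02d}")
                if out is not None:
                    candidates.append(out)

    if not candidates:
        raise RuntimeError(
            f"patient {patient.patient_id}: every fit candidate failed"
        )
    # lowest plain SSR wins; Python's min is stable, so ties keep the
    # first candidate in enumeration order
    ssr, x, r, ok, label = min(candidates, key=lambda c: c[0])
    converged = any(c[3] for c in candidates)
    params = DecayParameters(
        a=float(x[0]), b=float(x[1]), c=float(x[2]),
        tc=float(x[3]) - ga, ga_days=ga,
    )
    return FitResult(
        patient_id=patient.patient_id,
        params=params,
        composite=to_composite(params),
        residuals=r,
        rmse=float(np.sqrt(ssr / p.size)),
        ssr=ssr,
        n_samples=int(p.size),
        converged=converged,
        loss_config_used=label,
        seed=settings.seed,
        ga_days=ga,
    )


def fit_cohort(
    cohort: list[PatientRecord], settings: Optional[FitSettings] = None
) -> list[FitResult]:
    """Fit every patient; per-patient failures are collected, not fatal."""
    settings = settings or FitSettings()
    results = []
    for patient in cohort:
        try:
            fit = fit_patient(patient, settings)
        except ValueError:
            raise  # precondition violations signal upstream bugs
        except RuntimeError as exc:
            log.error("patient %s: %s", patient.patient_id, exc)
            continue
        log.debug(
            "patient %s: rmse=%.3f via %s",
            patient.patient_id, fit.rmse, fit.loss_config_used,
        )
        results.append(fit)
    return results


def fits_frame(fits: list[FitResult]):
    """Flatten patient-specific fits into the fits.csv schema."""
    import pandas as pd

    rows = []
    for f in sorted(fits, key=lambda f: f.patient_id):
        prm: DecayParameters = f.params
        rows.append(
            {
                "patient_id": f.patient_id,
                "A": prm.a,
                "B": prm.b,
                "C": prm.c,
                "Tc": prm.tc,
                "ga_days": prm.ga_days,
                "amplitude_tilde": f.composite.amplitude_tilde,
                "rmse": f.rmse,
                "ssr": f.ssr,
                "n_samples": f.n_samples,
                "converged": f.converged,
                "loss_config_used": f.loss_config_used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "A", "B", "C", "Tc", "ga_days", "amplitude_tilde",
            "rmse", "ssr", "n_samples", "converged", "loss_config_used",
        ],
    )
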