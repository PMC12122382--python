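"""Population-level analysis of fitted patient-specific models.

Covers the descriptive summaries of the fitted parameter distributions, the
median model (the decay curve built from across-patient parameter medians),
one-at-a-time local sensitivity sweeps around that median model, and the
comparison statistics used for cohort tables (chi-square for categorical
variables, Mann-Whitney U for continuous ones, Bonferroni-adjusted
significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PatientRecord
from .fitting import FitResult
from .models import DecayParameters, eval_patient_specific

__all__ = [
    "ParameterStats",
    "ParameterSummary",
    "summarize_parameters",
    "build_median_model",
    "SensitivitySweep",
    "sensitivity_sweep",
    "DEFAULT_SWEEP_RANGES",
    "pearson_tsb_pna",
    "mann_whitney_u",
    "chi_square",
    "bonferroni_alpha",
    "GroupComparison",
    "compare_groups",
    "DEFAULT_COMPARISON_VARIABLES",
]

log = logging.getLogger(__name__)


@dataclass
class ParameterStats:
    name: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    sd_degenerate: bool = False  # single observation: SD reported as 0


@dataclass
class ParameterSummary:
    """Per-parameter descriptive statistics over a cohort of fits."""

    stats: dict  # name -> ParameterStats

    def __getitem__(self, name: str) -> ParameterStats:
        return self.stats[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": s.name, "n": s.n, "mean": s.mean, "sd": s.sd,
                    "median": s.median, "q1": s.q1, "q3": s.q3,
                    "min": s.min, "max": s.max,
                }
                for s in self.stats.values()
            ],
            columns=["parameter", "n", "mean", "sd", "median", "q1", "q3",
                     "min", "max"],
        )


def _summarize(name: str, values: np.ndarray) -> ParameterStats:
    degenerate = values.size == 1
    sd = 0.0 if degenerate else float(np.std(values, ddof=1))
    # Freedman-Diaconis, falling back when the IQR collapses (e.g. C piled at 0)
    try:
        edges = np.histogram_bin_edges(values, bins="fd")
    except Exception:
        edges = np.histogram_bin_edges(values, bins="sturges")
    if edges.size < 2 or not np.all(np.isfinite(edges)):
        edges = np.histogram_bin_edges(values, bins="sturges")
    counts, edges = np.histogram(values, bins=edges)
    return ParameterStats(
        name=name,
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=sd,
        median=float(np.median(values)),
        q1=float(np.quantile(values, 0.25)),  # type-7 linear interpolation
        q3=float(np.quantile(values, 0.75)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        hist_edges=edges,
        hist_counts=counts,
        sd_degenerate=degenerate,
    )


def summarize_parameters(fits: list[FitResult]) -> ParameterSummary:
    """Summary statistics and histograms of A, B, C, Tc and RMSE."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to summarize")
    cols = {
        "A": np.array([f.params.a for f in converged]),
        "B": np.array([f.params.b for f in converged]),
        "C": np.array([f.params.c for f in converged]),
        "Tc": np.array([f.params.tc for f in converged]),
        "rmse": np.array([f.rmse for f in converged]),
    }
    return ParameterSummary({name: _summarize(name, v) for name, v in cols.items()})


def build_median_model(
    fits: list[FitResult], ga_days: Optional[float] = None
) -> DecayParameters:
    """Decay curve from across-patient medians of A, B, C and Tc.

    The curve needs a gestational age to evaluate; by default the median
    GA of the fitted patients is used (pass ``ga_days`` to override).
    """
    if not fits:
        raise ValueError("cannot build a median model from zero fits")
    med = lambda xs: float(np.median(np.array(xs)))  # noqa: E731
    ga = med([f.params.ga_days for f in fits]) if ga_days is None else float(ga_days)
    return DecayParameters(
        a=med([f.params.a for f in fits]),
        b=med([f.params.b for f in fits]),
        c=med([f.params.c for f in fits]),
        tc=med([f.params.tc for f in fits]),
        ga_days=ga,
    )


#: One-at-a-time sweep ranges; these intentionally exceed the fitting
#: bounds (the amplitude is explored to 400 and the asymptote down to -100).
DEFAULT_SWEEP_RANGES = {
    "A": (0.0, 400.0),
    "B": (0.0, 0.3),
    "C": (-100.0, 200.0),
    "Tc": (-215.0, -150.0),
}

_PARAM_FIELD = {"A": "a", "B": "b", "C": "c", "Tc": "tc"}


@dataclass
class SensitivitySweep:
    parameter: str
    grid: np.ndarray
    pna_grid: np.ndarray
    curves: np.ndarray  # shape (len(grid), len(pna_grid))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.curves.T,
            columns=[f"{self.parameter}={v:g}" for v in self.grid],
        )
        df.insert(0, "pna_days", self.pna_grid)
        return df


def sensitivity_sweep(
    median_params: DecayParameters,
    parameter: str,
    value_range: Optional[tuple[float, float]] = None,
    n_grid: int = 9,
    pna_grid: Optional[np.ndarray] = None,
) -> SensitivitySweep:
    """Vary one parameter of the median model over its range, others fixed."""
    if parameter not in _PARAM_FIELD:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of "
            f"{sorted(_PARAM_FIELD)}"
        )
    lo, hi = value_range if value_range is not None else DEFAULT_SWEEP_RANGES[parameter]
    grid = np.linspace(lo, hi, n_grid)
    if pna_grid is None:
        pna_grid = np.arange(0.0, 60.0 + 1e-9, 0.25)
    curves = np.empty((grid.size, pna_grid.size))
    for i, v in enumerate(grid):
        kwargs = {
            "a": median_params.a, "b": median_params.b, "c": median_params.c,
            "tc": median_params.tc, "ga_days": median_params.ga_days,
        }
        kwargs[_PARAM_FIELD[parameter]] = float(v)
        curves[i] = eval_patient_specific(DecayParameters(**kwargs), pna_grid)
    if not np.all(np.isfinite(curves)):
        raise ValueError("sensitivity sweep produced non-finite curve values")
    return SensitivitySweep(parameter, grid, np.asarray(pna_grid, float), curves)


def pearson_tsb_pna(samples: list) -> float:
    """Pearson correlation between TSB and PNA over pooled samples."""
    t = np.array([m.pna_days for m in samples], dtype=float)
    y = np.array([m.tsb_umol_l for m in samples], dtype=float)
    if t.size < 3:
        raise ValueError("Pearson correlation needs >= 3 samples")
    if np.ptp(t) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(t, y).statistic)


# ---------------------------------------------------------------------------
# comparison statistics


def mann_whitney_u(x, y) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U; returns (U, p, all_tied_flag).

    Exact null distribution when the smaller group has <= 8 observations and
    there are no cross-group ties; otherwise the normal approximation with
    tie correction.  Fully tied data yield p = 1 with the flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0, True
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), False


def chi_square(table) -> tuple[float, float]:
    """Chi-square test on a contingency table (Yates correction for 2x2)."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise ValueError("chi-square of an all-zero table is undefined")
    correction = table.shape == (2, 2)
    try:
        res = stats.chi2_contingency(table, correction=correction)
    except ValueError as exc:
        raise ValueError(f"chi-square failed: {exc}") from exc
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Per-test significance level after Bonferroni correction."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


@dataclass
class GroupComparison:
    variable: str
    kind: str  # "categorical" | "continuous"
    test: str  # "chi_square" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    note: str = ""


#: Variable name -> (kind, extractor) for cohort comparison tables.
DEFAULT_COMPARISON_VARIABLES: dict[str, tuple[str, Callable]] = {
    "sex": ("categorical", lambda p: p.sex),
    "ga_days": ("continuous", lambda p: p.ga_days),
    "birth_weight_g": ("continuous", lambda p: p.birth_weight_g),
    "n_measurements": ("continuous", lambda p: len(p.measurements)),
}


def compare_groups(
    cohort_a: list[PatientRecord],
    cohort_b: list[PatientRecord],
    variables: Optional[dict] = None,
    n_comparisons: int = 20,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Compare two cohorts variable by variable.

    Categorical variables use the chi-square test on the 2 x k contingency
    table; continuous variables use the two-sided Mann-Whitney U test.
    Significance is judged at ``alpha / n_comparisons``.
    """
    variables = variables if variables is not None else DEFAULT_COMPARISON_VARIABLES
    adj = bonferroni_alpha(alpha, n_comparisons)
    results = []
    for name, (kind, extract) in variables.items():
        va = [extract(p) for p in cohort_a if extract(p) is not None]
        vb = [extract(p) for p in cohort_b if extract(p) is not None]
        if not va or not vb:
            results.append(
                GroupComparison(name, kind, "none", float("nan"), float("nan"),
                                False, note="missing data")
            )
            continue
        if kind == "categorical":
            cats = sorted(set(va) | set(vb))
            table = np.array(
                [[sum(v == c for v in va) for c in cats],
                 [sum(v == c for v in vb) for c in cats]]
            )
            stat, p = chi_square(table)
            results.append(
                GroupComparison(name, kind, "chi_square", stat, p, p < adj)
            )
        else:
            stat, p, tied = mann_whitney_u(va, vb)
            results.append(
                GroupComparison(
                    name, kind, "mann_whitney", stat, p, p < adj,
                    note="all values tied" if tied else "",
                )
            )
    log.info("compared %d variables at adjusted alpha %.4g", len(results), adj)
    return results


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": c.variable, "kind": c.kind, "test": c.test,
                "statistic": c.statistic, "p_value": c.p_value,
                "significant": c.significant, "note": c.note,
            }
            for c in comparisons
        ],
        columns=["variable", "kind", "test", "statistic", "p_value",
                 "significant", "note"],
    )
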