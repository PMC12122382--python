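"""Bilirubin decay-curve mathematics.

Three nested descriptions of the postnatal decline of total serum bilirubin
(TSB) are used:

* a population linear trend ``TSB(t) = A + B t``,
* a population exponential decay ``TSB(t) = A exp(-B t) + C``,
* the patient-specific, gestational-age-shifted exponential decay

  .. math:: y_i(t) = A_i \\exp(-B_i [p_i(t) + GA_i + Tc_i]) + C_i

  where ``p_i(t)`` is postnatal age in days, ``GA_i`` gestational age at
  birth in days, and ``Tc_i`` a patient-specific time-correction that brings
  the combined shift ``GA + Tc`` back to the order of days (GA alone is
  ~200 days, so fitted ``Tc`` is large and negative).

The patient-specific curve is over-parameterized: ``A`` and ``Tc`` enter the
mean only through the composite amplitude ``Ã = A exp(-B (GA + Tc))``, so
the identifiable description of a curve is ``(Ã, B, C)``
(:class:`CompositeParameters`).  Raw parameters are kept for fitting and
reporting; recovery claims are only ever made about the composite set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearParams",
    "GeneralExpParams",
    "DecayParameters",
    "CompositeParameters",
    "eval_linear",
    "eval_general_exponential",
    "eval_patient_specific",
    "to_composite",
    "rmse",
]

#: exponent magnitude beyond which exp() is refused rather than overflowed
_EXP_LIMIT = 700.0


@dataclass(frozen=True)
class LinearParams:
    """Population linear trend: intercept (µmol/L) and slope (µmol/L/day)."""

    intercept_a: float
    slope_b: float


@dataclass(frozen=True)
class GeneralExpParams:
    """Population exponential decay: amplitude, rate (1/day), asymptote."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class DecayParameters:
    """Patient-specific decay-curve parameters.

    Attributes
    ----------
    a : amplitude, µmol/L (fitting bound [0, 200])
    b : decay rate, 1/day (fitting bound [0, 1.5])
    c : asymptote, µmol/L (non-negative under fitting bounds)
    tc : time-correction, days (large negative in practice)
    ga_days : gestational age at birth, days
    """

    a: float
    b: float
    c: float
    tc: float
    ga_days: float

    @property
    def delta(self) -> float:
        """Combined time shift GA + Tc, days; the identifiable offset."""
        return self.ga_days + self.tc


@dataclass(frozen=True)
class CompositeParameters:
    """Identifiable reparameterization (Ã, B, C) with Ã = A·exp(−B·(GA+Tc))."""

    amplitude_tilde: float
    b: float
    c: float


def eval_linear(params: LinearParams, t):
    """Evaluate the linear trend at PNA ``t`` (days)."""
    return params.intercept_a + params.slope_b * np.asarray(t, dtype=float)


def eval_general_exponential(params: GeneralExpParams, t):
    """Evaluate ``A exp(-B t) + C`` at PNA ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    return params.a * np.exp(-params.b * t) + params.c


def eval_patient_specific(params: DecayParameters, p):
    """Evaluate the patient-specific curve at PNA ``p`` (days).

    Computes the exponent as ``-B (p + GA + Tc)`` without pre-reducing to
    composite form so that fitted (A, Tc) pairs round-trip exactly.
    """
    p = np.asarray(p, dtype=float)
    return params.a * np.exp(-params.b * (p + params.ga_days + params.tc)) + params.c


def to_composite(params: DecayParameters) -> CompositeParameters:
    """Collapse (A, Tc) into the identifiable amplitude Ã = A·exp(−B·(GA+Tc)).

    Raises
    ------
    OverflowError
        If ``-B (GA + Tc)`` is large enough that exp() would overflow;
        the message names the offending exponent.
    """
    exponent = -params.b * (params.ga_days + params.tc)
    if exponent > _EXP_LIMIT:
        raise OverflowError(
            f"composite amplitude overflows: exponent -B*(GA+Tc) = {exponent:.3g}"
        )
    return CompositeParameters(
        amplitude_tilde=params.a * np.exp(exponent), b=params.b, c=params.c
    )


def rmse(observed, predicted) -> float:
    """Root-mean-square error between observed and predicted TSB, µmol/L."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: observed {observed.shape} vs predicted "
            f"{predicted.shape}"
        )
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))
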