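"""Population summaries, median model, sensitivity sweeps, comparison stats."""

import numpy as np
import pytest

from conftest import make_patient
from tsbdecay.analysis import (
    bonferroni_alpha,
    build_median_model,
    chi_square,
    compare_groups,
    mann_whitney_u,
    pearson_tsb_pna,
    sensitivity_sweep,
    summarize_parameters,
)
from tsbdecay.datatypes import TsbMeasurement
from tsbdecay.fitting import FitResult
from tsbdecay.models import (
    DecayParameters,
    eval_patient_specific,
    to_composite,
)


def _fit(pid, a, b, c, tc, ga=196.0, rmse_val=5.0, n=5):
    params = DecayParameters(a=a, b=b, c=c, tc=tc, ga_days=ga)
    ssr = rmse_val**2 * n
    return FitResult(
        patient_id=pid,
        params=params,
        composite=to_composite(params),
        residuals=np.zeros(n) + rmse_val,
        rmse=rmse_val,
        ssr=ssr,
        n_samples=n,
        converged=True,
        loss_config_used="linear|start00",
    )


THREE_FITS = [
    _fit("a", 100.0, 0.1, 0.0, -190.0),
    _fit("b", 120.0, 0.1, 0.0, -195.0),
    _fit("c", 140.0, 0.1, 30.0, -200.0),
]


class TestSummaries:
    def test_basic_statistics(self):
        summary = summarize_parameters(THREE_FITS)
        assert summary["A"].mean == pytest.approx(120.0)
        assert summary["A"].median == pytest.approx(120.0)
        assert summary["C"].median == pytest.approx(0.0)
        assert summary["A"].hist_counts.sum() == 3
        assert summary["A"].q1 <= summary["A"].median <= summary["A"].q3

    def test_single_fit_sd_flagged(self):
        summary = summarize_parameters(THREE_FITS[:1])
        assert summary["A"].sd == 0.0
        assert summary["A"].sd_degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_parameters([])


class TestMedianModel:
    def test_componentwise_medians(self):
        med = build_median_model(THREE_FITS)
        assert med.a == pytest.approx(120.0)
        assert med.b == pytest.approx(0.1)
        assert med.c == pytest.approx(0.0)
        assert med.tc == pytest.approx(-195.0)

    def test_single_fit_is_identity(self):
        med = build_median_model(THREE_FITS[:1])
        assert med == THREE_FITS[0].params

    def test_median_curve_is_finite_and_decaying(self):
        med = build_median_model(THREE_FITS)
        p = np.arange(0, 60, 0.25)
        y = eval_patient_specific(med, p)
        assert np.all(np.isfinite(y))
        assert np.all(np.diff(y) < 0)


class TestSensitivity:
    median = DecayParameters(a=120.0, b=0.11, c=5.0, tc=-193.0, ga_days=195.0)

    def test_asymptote_sweep_is_pure_offset(self):
        sweep = sensitivity_sweep(self.median, "C", value_range=(0.0, 50.0),
                                  n_grid=2)
        diff = sweep.curves[1] - sweep.curves[0]
        assert np.allclose(diff, 50.0)

    def test_time_shift_sweep_moves_curve_rightward(self):
        pna = np.arange(0.0, 40.0, 0.5)
        sweep = sensitivity_sweep(self.median, "Tc",
                                  value_range=(-193.0, -183.0), n_grid=2,
                                  pna_grid=pna)
        # curve at Tc-10... index 0 is Tc=-193, index 1 is Tc=-183 (+10)
        # shifting Tc by +10 equals evaluating 10 days later
        shift = 10.0
        idx = int(shift / 0.5)
        assert np.allclose(sweep.curves[1][:-idx], sweep.curves[0][idx:],
                           rtol=1e-9)

    def test_faster_decay_lowers_curve(self):
        sweep = sensitivity_sweep(self.median, "B", value_range=(0.05, 0.3),
                                  n_grid=4, pna_grid=np.arange(0.0, 40.0, 1.0))
        # on the domain where p + GA + Tc > 0, larger B means lower values
        positive = np.arange(0.0, 40.0, 1.0) + 195.0 - 193.0 > 0
        for lo, hi in zip(sweep.curves, sweep.curves[1:]):
            assert np.all(hi[positive] < lo[positive])

    def test_ranges_may_exceed_fitting_bounds(self):
        sweep = sensitivity_sweep(self.median, "A")
        assert sweep.grid[0] == 0.0 and sweep.grid[-1] == 400.0
        sweep_c = sensitivity_sweep(self.median, "C")
        assert sweep_c.grid[0] == -100.0

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            sensitivity_sweep(self.median, "GA")


class TestPearson:
    def _samples(self, ts, ys):
        return [TsbMeasurement("x", t, y) for t, y in zip(ts, ys)]

    def test_perfect_negative_and_positive(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_tsb_pna(self._samples(t, 200 - 4 * t)) == pytest.approx(-1.0)
        assert pearson_tsb_pna(self._samples(t, 5 * t)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        samples = self._samples([0, 1, 2, 3], [0, 1, 0, 1])
        assert pearson_tsb_pna(samples) == pytest.approx(1 / np.sqrt(5))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_tsb_pna(self._samples([1, 2, 3], [5, 5, 5]))


class TestComparisonStats:
    def test_exact_mann_whitney_from_enumeration(self):
        # U = 0; all 20 assignments of ranks -> two-sided p = 2/20
        _, p, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_tied_data_flagged(self):
        _, p, tied = mann_whitney_u([3, 3, 3], [3, 3])
        assert p == 1.0 and tied

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.5, 3.0, 4.1, 7.0, 9.2, 10.0, 12.0, 13.5]
        _, p, _ = mann_whitney_u(x, x)
        assert p >= 0.99

    def test_balanced_table_has_no_association(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_bonferroni_threshold(self):
        assert bonferroni_alpha(0.05, 20) == pytest.approx(0.0025)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_cohort_compared_with_itself(self):
        cohort = [
            make_patient(f"p{i}", ga_days=170.0 + 3 * i,
                         pna_tsb=[(4 + j, 100.0) for j in range(4 + i % 3)],
                         sex="M" if i % 2 else "F",
                         birth_weight_g=900.0 + 40 * i)
            for i in range(10)
        ]
        for comp in compare_groups(cohort, cohort, n_comparisons=20):
            assert comp.p_value >= 0.99
            assert not comp.significant
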