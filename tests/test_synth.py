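"""Synthetic-cohort generator: determinism, bounds, calibrated distributions."""

import numpy as np
import pytest
from scipy import stats

from tsbdecay.models import eval_patient_specific
from tsbdecay.synth import (
    ConfigurationError,
    EventSpec,
    GeneratorSettings,
    PatientTruth,
    generate_cohort,
    generate_schedule,
    inject_event,
    sample_patient_parameters,
    simulate_trajectory,
    truncnorm_mean,
)


def test_parameters_respect_fitting_bounds():
    settings = GeneratorSettings()
    for seed in range(30):
        rng = np.random.default_rng(seed)
        params, noise_sd = sample_patient_parameters(rng, settings, ga_days=190.0)
        assert 0.0 <= params.a <= 200.0
        assert 0.0 <= params.b <= 1.5
        assert params.c >= 0.0
        assert noise_sd > 0.0


def test_degenerate_mixture_forces_zero_asymptote():
    settings = GeneratorSettings(c_zero_fraction=1.0)
    rng = np.random.default_rng(0)
    cs = [sample_patient_parameters(rng, settings, 190.0)[0].c for _ in range(50)]
    assert cs == [0.0] * 50


def test_invalid_settings_raise():
    with pytest.raises(ConfigurationError):
        sample_patient_parameters(
            np.random.default_rng(0), GeneratorSettings(a_sd=0.0), 190.0
        )
    with pytest.raises(ConfigurationError):
        GeneratorSettings(event_fraction=1.5).validate()


def test_amplitude_draws_match_truncated_normal_mean():
    """MC mean of A vs. the analytic truncated-normal mean (scipy oracle)."""
    settings = GeneratorSettings()
    rng = np.random.default_rng(123)
    draws = np.array(
        [sample_patient_parameters(rng, settings, 190.0)[0].a for _ in range(10_000)]
    )
    expected = truncnorm_mean(120.9, 27.54, 0.0, 200.0)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - expected) < 3 * se
    # the configured truncation barely moves the mean off 120.9
    assert expected == pytest.approx(120.9, abs=1.0)


def test_zero_asymptote_fraction_matches_mixture_weight():
    settings = GeneratorSettings()
    rng = np.random.default_rng(7)
    cs = np.array(
        [sample_patient_parameters(rng, settings, 190.0)[0].c for _ in range(10_000)]
    )
    frac = np.mean(cs == 0.0)
    se = np.sqrt(0.75 * 0.25 / cs.size)
    assert abs(frac - 0.75) < 3 * se


class TestSchedule:
    def test_lengths_and_monotonicity(self):
        settings = GeneratorSettings()
        for seed in range(50):
            sched = generate_schedule(np.random.default_rng(seed), settings)
            assert 4 <= len(sched) <= 20
            assert sched[0] >= 3.0
            gaps = np.diff(sched)
            assert np.all(gaps > 0)
            assert np.all(gaps <= settings.schedule_max_gap_days + 1e-12)

    def test_fixed_settings_give_deterministic_schedule(self):
        settings = GeneratorSettings(n_fixed=4, first_pna_fixed=4.0, gap_fixed=2.0)
        sched = generate_schedule(np.random.default_rng(0), settings)
        assert sched == [4.0, 6.0, 8.0, 10.0]

    def test_median_count_matches_configured_distribution(self):
        settings = GeneratorSettings()
        rng = np.random.default_rng(42)
        counts = [len(generate_schedule(rng, settings)) for _ in range(10_000)]
        assert np.median(counts) in (4, 5, 6)
        q1, q3 = np.percentile(counts, [25, 75])
        assert q1 >= 4 and q3 <= 7


class TestTrajectory:
    params_kw = dict(a=120.0, b=0.12, c=10.0, tc=-188.0, ga_days=195.0)

    def test_zero_noise_lies_on_curve(self):
        from tsbdecay.models import DecayParameters

        params = DecayParameters(**self.params_kw)
        sched = [4.0, 6.0, 9.0, 14.0]
        meas, n_clipped = simulate_trajectory(
            params, sched, 0.0, np.random.default_rng(0), "X"
        )
        expected = eval_patient_specific(params, np.array(sched))
        assert np.allclose([m.tsb_umol_l for m in meas], expected)
        assert n_clipped == 0

    def test_event_bump_is_additive(self):
        from tsbdecay.models import DecayParameters

        params = DecayParameters(**self.params_kw)
        sched = [4.0, 8.0, 15.0, 20.0]
        event = EventSpec(center_pna=15.0, amplitude=80.0, width=2.0)
        meas, _ = simulate_trajectory(
            params, sched, 0.0, np.random.default_rng(0), "X", event=event
        )
        base = eval_patient_specific(params, 15.0)
        assert meas[2].tsb_umol_l == pytest.approx(base + 80.0)

    def test_fixed_seed_reproduces_measurements(self):
        from tsbdecay.models import DecayParameters

        params = DecayParameters(**self.params_kw)
        sched = [4.0, 6.0, 9.0]
        a, _ = simulate_trajectory(params, sched, 8.0, np.random.default_rng(5), "X")
        b, _ = simulate_trajectory(params, sched, 8.0, np.random.default_rng(5), "X")
        assert a == b


class TestInjectEvent:
    def _patient_and_truth(self, seed=0):
        settings = GeneratorSettings(n_patients=1, seed=seed, event_fraction=0.0,
                                     pt_fraction=0.0)
        cohort, truth = generate_cohort(settings)
        return cohort[0], truth[cohort[0].patient_id], settings

    def test_zero_amplitude_changes_only_crp(self):
        patient, truth, settings = self._patient_and_truth()
        settings.event_amplitude_range = (0.0, 0.0)
        injected, new_truth = inject_event(
            patient, truth, np.random.default_rng(1), settings
        )
        assert [m.tsb_umol_l for m in injected.measurements] == pytest.approx(
            [m.tsb_umol_l for m in patient.measurements]
        )
        assert len(injected.crp) == len(patient.crp) + 1
        assert injected.crp[-1].crp_mg_l > 5.0
        assert new_truth.event_injected

    def test_bump_added_at_center(self):
        patient, truth, settings = self._patient_and_truth()
        center = patient.measurements[-1].pna_days
        settings.event_center_range = (center, center)
        settings.event_amplitude_range = (80.0, 80.0)
        injected, _ = inject_event(patient, truth, np.random.default_rng(1), settings)
        delta = (injected.measurements[-1].tsb_umol_l
                 - patient.measurements[-1].tsb_umol_l)
        assert delta == pytest.approx(80.0)

    def test_out_of_span_center_is_shifted(self):
        patient, truth, settings = self._patient_and_truth()
        settings.event_center_range = (500.0, 500.0)
        injected, new_truth = inject_event(
            patient, truth, np.random.default_rng(1), settings
        )
        assert new_truth.event_center_pna == patient.measurements[-1].pna_days


class TestGenerateCohort:
    def test_cohort_is_reproducible(self):
        settings = GeneratorSettings(n_patients=10, seed=42)
        a, truth_a = generate_cohort(settings)
        b, truth_b = generate_cohort(settings)
        assert a == b
        assert all(
            truth_a[p.patient_id].params == truth_b[p.patient_id].params
            for p in a
        )

    def test_early_patients_stable_under_cohort_growth(self):
        small, _ = generate_cohort(
            GeneratorSettings(n_patients=5, seed=9, event_fraction=0.0,
                              pt_fraction=0.0)
        )
        large, _ = generate_cohort(
            GeneratorSettings(n_patients=9, seed=9, event_fraction=0.0,
                              pt_fraction=0.0)
        )
        for a, b in zip(small, large):
            assert a.measurements == b.measurements

    def test_event_fraction_zero_means_no_events(self):
        _, truth = generate_cohort(
            GeneratorSettings(n_patients=12, seed=1, event_fraction=0.0)
        )
        assert not any(t.event_injected for t in truth.patients.values())

    def test_ga_within_study_window(self):
        cohort, _ = generate_cohort(GeneratorSettings(n_patients=72, seed=3))
        assert all(168.0 <= p.ga_days < 224.0 for p in cohort)

    def test_event_count_is_exact(self):
        _, truth = generate_cohort(
            GeneratorSettings(n_patients=72, seed=5, event_fraction=12 / 72)
        )
        assert sum(t.event_injected for t in truth.patients.values()) == 12
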