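import numpy as np
import pytest

from circasync.fftnlls import (
    CosComponent,
    RhythmFit,
    circadian_phase,
    fit_fft_nlls,
    relative_amplitude_error,
)


def make_fit(period=25.5, amplitude=10.0, phase=6.0, se_amplitude=0.5):
    comp = CosComponent(period, amplitude, phase, 0.01, se_amplitude, 0.01)
    return RhythmFit(components=[comp], selected=0, status="ok")


class TestFitRecovery:
    def test_noiseless_exact_recovery(self, hourly_week, pure_cosine):
        fit = fit_fft_nlls(pure_cosine, hourly_week)
        assert fit.status == "ok"
        assert fit.period_hours == pytest.approx(25.5, abs=0.01)
        assert fit.phase_hours == pytest.approx(6.0, abs=0.01)
        assert fit.amplitude == pytest.approx(10.0, abs=0.01)
        assert relative_amplitude_error(fit) < 0.01

    def test_noisy_recovery_is_accurate(self, hourly_week, pure_cosine):
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = pure_cosine + rng.normal(0, 1, size=168)
            fit = fit_fft_nlls(y, hourly_week)
            assert fit.status == "ok"
            errors.append(abs(fit.period_hours - 25.5))
        assert np.median(errors) < 0.3

    def test_harmonic_fitted_but_not_selected(self, hourly_week):
        y = np.cos(2 * np.pi * hourly_week / 24) + 0.5 * np.cos(2 * np.pi * hourly_week / 12)
        fit = fit_fft_nlls(y, hourly_week)
        assert fit.status == "ok"
        assert fit.period_hours == pytest.approx(24.0, abs=0.05)
        periods = [c.period_hours for c in fit.components]
        assert any(abs(p - 12) < 0.5 for p in periods)

    def test_no_circadian_component_flagged(self, hourly_week):
        y = np.cos(2 * np.pi * hourly_week / 8)  # ultradian only
        fit = fit_fft_nlls(y, hourly_week, circadian_window=(18, 34))
        assert fit.status == "no_circadian_component"

    def test_constant_series_has_no_component(self, hourly_week):
        fit = fit_fft_nlls(np.full(168, 5.0), hourly_week)
        assert fit.status != "ok"

    def test_linear_trend_removed(self, hourly_week, pure_cosine):
        fit = fit_fft_nlls(pure_cosine + 2.0 * hourly_week, hourly_week)
        assert fit.period_hours == pytest.approx(25.5, abs=0.02)


class TestInvariances:
    def test_time_shift_equivariance(self, hourly_week):
        tau = 24.0
        y0 = np.cos(2 * np.pi * hourly_week / tau)
        delta = 5.0
        y1 = np.cos(2 * np.pi * (hourly_week - delta) / tau)
        f0 = fit_fft_nlls(y0, hourly_week)
        f1 = fit_fft_nlls(y1, hourly_week)
        shift = (f1.phase_hours - f0.phase_hours) % f0.period_hours
        assert shift == pytest.approx(delta, abs=0.01)

    def test_rae_scale_invariance(self, hourly_week, pure_cosine):
        rng = np.random.default_rng(2)
        y = pure_cosine + rng.normal(0, 1, 168)
        r1 = relative_amplitude_error(fit_fft_nlls(y, hourly_week))
        r3 = relative_amplitude_error(fit_fft_nlls(3.0 * y, hourly_week))
        assert r1 == pytest.approx(r3, abs=1e-9)

    def test_rss_monotone_in_components(self, hourly_week):
        rng = np.random.default_rng(4)
        y = (np.cos(2 * np.pi * hourly_week / 25)
             + 0.6 * np.cos(2 * np.pi * (hourly_week - 3) / 12.2)
             + 0.3 * rng.normal(size=168))
        rss = []
        for k in (1, 2, 3):
            fit = fit_fft_nlls(y, hourly_week, max_components=k)
            rss.append(fit.rss)
        assert rss[0] >= rss[1] >= rss[2]


class TestRelativeAmplitudeError:
    def test_definition(self):
        assert relative_amplitude_error(make_fit(se_amplitude=2.0)) == pytest.approx(0.2)

    def test_clipped_at_one(self):
        assert relative_amplitude_error(make_fit(amplitude=1.0, se_amplitude=5.0)) == 1.0

    def test_requires_ok_status(self):
        fit = RhythmFit(components=[], selected=None, status="non_convergent")
        with pytest.raises(ValueError, match="non_convergent"):
            relative_amplitude_error(fit)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="zero amplitude"):
            relative_amplitude_error(make_fit(amplitude=0.0))


class TestCircadianPhase:
    def test_circadian_normalization(self):
        fit = make_fit(period=25.5, phase=6.0)
        assert circadian_phase(fit, 24.0) == pytest.approx(6 * 24 / 25.5)

    def test_phase_reduced_modulo_period(self):
        fit = make_fit(period=25.5, phase=30.0)
        assert circadian_phase(fit, None) == pytest.approx(4.5)

    def test_normalize_to_period_is_identity(self):
        fit = make_fit(period=25.5, phase=6.0)
        assert circadian_phase(fit, 25.5) == pytest.approx(6.0)
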