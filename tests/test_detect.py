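import itertools
import math

import numpy as np
import pytest
from scipy import signal as sp_signal

from circasync import LightRegime, SimParams, simulate_panel
from circasync.detect import (
    DetectConfig,
    bh_qvalues,
    call_rhythmic,
    detect_panel,
    fisher_combine,
    jtk_cycle_test,
    lomb_scargle_test,
    ls_periodogram,
)


def brute_force_bh(p):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q_sorted[rank_i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(rank_i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestLombScargle:
    def test_pure_cosine_maximally_significant(self, hourly_week):
        y = np.cos(2 * np.pi * hourly_week / 24)
        period, p = lomb_scargle_test(y, hourly_week, n_perm=200, seed=0)
        assert abs(period - 24.0) <= 0.1
        assert p == pytest.approx(1 / 201)

    def test_constant_series_not_significant(self, hourly_week):
        period, p = lomb_scargle_test(np.full(168, 3.0), hourly_week)
        assert p == 1.0
        assert np.isnan(period)

    def test_agrees_with_scipy_periodogram(self, hourly_week):
        """Independent oracle: scipy's Lomb-Scargle finds the same peak and
        a proportional power profile on a noisy damped oscillation."""
        rng = np.random.default_rng(3)
        t = hourly_week
        y = 2 ** (-t / 100) * np.cos(2 * np.pi * (t - 4) / 26.5) + 0.4 * rng.normal(size=t.size)
        periods = np.arange(18, 34.05, 0.1)
        mine = ls_periodogram(y, t, periods)
        theirs = sp_signal.lombscargle(t, y - y.mean(), 2 * np.pi / periods, normalize=True)
        assert periods[np.argmax(mine)] == periods[np.argmax(theirs)]
        assert np.corrcoef(mine, theirs)[0, 1] > 0.999

    def test_invalid_period_range_rejected(self, hourly_week):
        y = np.cos(2 * np.pi * hourly_week / 24)
        with pytest.raises(ValueError, match="period_range"):
            lomb_scargle_test(y, hourly_week, period_range_hours=(1.0, 34.0))

    def test_seeded_reproducibility(self, hourly_week):
        rng = np.random.default_rng(9)
        y = rng.normal(size=168)
        a = lomb_scargle_test(y, hourly_week, seed=42)
        b = lomb_scargle_test(y, hourly_week, seed=42)
        assert a == b


class TestJtkCycle:
    def test_cosine_detected_at_its_period_and_lag(self, hourly_week):
        y = np.cos(2 * np.pi * (hourly_week - 6) / 24)
        period, lag, p = jtk_cycle_test(y, hourly_week)
        assert period == 24.0
        assert lag == 6.0
        assert p < 1e-20

    def test_sign_flip_selects_antiphase_lag(self, hourly_week):
        y = np.cos(2 * np.pi * hourly_week / 24)
        p_pos = jtk_cycle_test(y, hourly_week)
        p_neg = jtk_cycle_test(-y, hourly_week)
        assert p_neg[1] == pytest.approx((p_pos[1] + 12.0) % 24.0)
        # same order of significance for the mirrored series
        assert np.log(p_neg[2]) == pytest.approx(np.log(p_pos[2]), rel=0.2)

    def test_constant_series_p_one(self, hourly_week):
        period, lag, p = jtk_cycle_test(np.ones(168), hourly_week)
        assert p == 1.0

    def test_exact_null_matches_exhaustive_permutations(self):
        """At n=8 the one-sided p (before Bonferroni) equals the exhaustive
        permutation null P(S_perm >= S_obs) for a tie-free reference."""
        t = np.arange(8.0)
        ref = np.cos(2 * np.pi * t / 8.5)  # tie-free reference values
        rng = np.random.default_rng(0)
        iu, ju = np.triu_indices(8, k=1)
        sr = np.sign(ref[iu] - ref[ju])
        perms = np.array(list(itertools.permutations(range(8))), dtype=float)
        s_null = np.sign(perms[:, iu] - perms[:, ju]) @ sr

        for _ in range(5):
            series = rng.permutation(8).astype(float)
            s_obs = np.sign(series[iu] - series[ju]) @ sr
            p_oracle = np.mean(s_null >= s_obs)
            _, _, p = jtk_cycle_test(series, t, period_grid_hours=[8.5], lag_step_hours=100.0)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_minimal_p_attained_by_perfect_concordance(self):
        t = np.arange(8.0)
        ref = np.cos(2 * np.pi * t / 8.5)
        series = np.argsort(np.argsort(ref)).astype(float)  # same ranks as ref
        _, _, p = jtk_cycle_test(series, t, period_grid_hours=[8.5], lag_step_hours=100.0)
        assert p == pytest.approx(1 / math.factorial(8), abs=1e-12)


class TestFisherCombine:
    def test_half_half(self):
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-3)

    def test_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_identity_for_single_p(self):
        for p in (0.01, 0.3, 0.77):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_zero_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = fisher_combine([0.0, 0.5])
        assert 0 <= p < 1e-100


class TestBhQvalues:
    def test_worked_example(self):
        q = bh_qvalues([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.8], rtol=1e-5)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_qvalues([0.3, 0.3, 0.3]), 0.3)

    def test_single_p_identity(self):
        assert bh_qvalues([0.123])[0] == pytest.approx(0.123)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_qvalues(p), brute_force_bh(p), atol=1e-12)


class TestCallRhythmic:
    def _calls(self, qs, periods):
        import pandas as pd

        return pd.DataFrame(
            {
                "replicate_id": [f"r{i}" for i in range(len(qs))],
                "q": qs,
                "period_detected_hours": periods,
            }
        )

    def test_counting(self):
        qs = [1e-5] * 6 + [0.5] * 4
        periods = [24.0] * 10
        _, fraction = call_rhythmic(self._calls(qs, periods))
        assert fraction == 0.6

    def test_threshold_is_strict(self):
        flagged, _ = call_rhythmic(self._calls([0.001], [24.0]))
        assert not flagged["rhythmic"].iloc[0]

    def test_period_bounds_closed(self):
        flagged, _ = call_rhythmic(self._calls([1e-6] * 3, [18.0, 34.0, 34.1]))
        assert flagged["rhythmic"].tolist() == [True, True, False]


def test_detect_panel_flags_strong_oscillators(small_frl_panel):
    from circasync.preprocess import preprocess_panel

    clean = preprocess_panel(small_frl_panel)
    calls, fraction = detect_panel(clean, DetectConfig(n_perm=100, seed=1))
    assert set(calls.columns) >= {
        "replicate_id", "p_ls", "p_jtk", "p_combined", "q",
        "period_detected_hours", "rhythmic",
    }
    assert fraction == 1.0
    assert calls["period_detected_hours"].between(18, 34).all()


def test_detect_panel_seed_determinism(small_frl_panel):
    from circasync.preprocess import preprocess_panel

    clean = preprocess_panel(small_frl_panel)
    a, _ = detect_panel(clean, DetectConfig(n_perm=50, seed=3))
    b, _ = detect_panel(clean, DetectConfig(n_perm=50, seed=3))
    assert a.equals(b)
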