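import numpy as np
import pytest
from scipy import stats

from circasync import LightRegime, TimeSeriesSet
from circasync.detect import DetectConfig
from circasync.fftnlls import FitConfig
from circasync.preprocess import DetrendConfig, preprocess_panel
from circasync.synth import simulate_panel, ztc_preset
from circasync.tcycle_groups import (
    compact_letter_display,
    compare_groups,
    normalize_phase_to_24,
    period_vs_T,
)


class TestNormalizePhase:
    @pytest.mark.parametrize(
        "phase, T, expected",
        [(14.0, 28.0, 12.0), (10.0, 20.0, 12.0), (6.0, 24.0, 6.0), (0.0, 22.0, 0.0)],
    )
    def test_values(self, phase, T, expected):
        assert normalize_phase_to_24(phase, T) == pytest.approx(expected)

    def test_out_of_range_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="modulo"):
            out = normalize_phase_to_24(30.0, 28.0)
        assert out == pytest.approx(2.0 * 24 / 28)

    def test_order_preserved_within_cycle(self):
        phases = np.array([1.0, 5.0, 9.0, 19.0])
        out = normalize_phase_to_24(phases, 20.0)
        assert np.all(np.diff(out) > 0)


class TestCompareGroups:
    def test_identical_groups_share_a_letter(self):
        res = compare_groups({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert res.F_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.tukey_letters["a"] == res.tukey_letters["b"]

    def test_distant_group_gets_distinct_letter(self):
        res = compare_groups(
            {"g1": [1.0, 2, 3], "g2": [1.0, 2, 3], "g3": [10.0, 11, 12]}
        )
        # textbook one-way ANOVA on these nine values
        f_expected, p_expected = stats.f_oneway([1, 2, 3], [1, 2, 3], [10, 11, 12])
        assert res.F_statistic == pytest.approx(f_expected)
        assert res.p_anova == pytest.approx(p_expected)
        assert res.tukey_letters["g1"] == res.tukey_letters["g2"]
        assert res.tukey_letters["g3"] != res.tukey_letters["g1"]

    def test_permutation_invariance_of_grouping(self):
        data = {"x": [1.0, 2, 3], "y": [1.5, 2.5, 3.5], "z": [20.0, 21, 22]}
        res1 = compare_groups(data)
        res2 = compare_groups(dict(reversed(list(data.items()))))
        same1 = res1.tukey_letters["x"] == res1.tukey_letters["y"]
        same2 = res2.tukey_letters["x"] == res2.tukey_letters["y"]
        assert same1 == same2
        assert (res1.tukey_letters["z"] == res1.tukey_letters["x"]) == (
            res2.tukey_letters["z"] == res2.tukey_letters["x"]
        )

    def test_letters_consistent_with_pairwise_decisions(self):
        rng = np.random.default_rng(8)
        groups = {
            f"g{i}": rng.normal(loc=mu, scale=1.0, size=8)
            for i, mu in enumerate([0.0, 0.5, 4.0, 4.2])
        }
        res = compare_groups(groups)
        for row in res.tukey_pairwise.itertuples():
            shared = set(res.tukey_letters[row.group1]) & set(res.tukey_letters[row.group2])
            assert bool(shared) == (not row.reject)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups({"only": [1.0, 2, 3]})

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0, 2], "b": [3.0]})

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups({"a": [1.0, 1.0], "b": [1.0, 1.0]})


def test_compact_letter_display_chain():
    # a ~ b, b ~ c, but a != c: classic overlapping chain needs two letters
    labels = ["a", "b", "c"]
    sig = {("a", "c"): True, ("a", "b"): False, ("b", "c"): False}
    letters = compact_letter_display(labels, sig)
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])


class TestPeriodVsT:
    def test_entrained_panels_track_cycle_length(self):
        panels = {}
        for T in (20.0, 28.0):
            params, regime = ztc_preset(seed=2, T_hours=T, n_reps=6, noise_sd=0.5)
            cfg = DetrendConfig(baseline_window_hours=T, amplitude_window_hours=T)
            panels[T] = preprocess_panel(simulate_panel(params, regime), cfg)
        table = period_vs_T(
            panels,
            DetectConfig(n_perm=60, seed=2),
            FitConfig(max_components=2),
        )
        for row in table.itertuples():
            assert row.n_rhythmic == 6
            assert abs(row.mean_period_hours - row.T_hours) < 0.2

    def test_panel_without_rhythmic_replicates_flagged(self):
        times = np.arange(0.0, 168.0)
        flat = TimeSeriesSet(
            times=times,
            signals=np.ones((3, 168)),
            regime=LightRegime("ZTC", 24, 12),
        )
        table = period_vs_T({24.0: flat}, DetectConfig(n_perm=20, seed=0))
        assert bool(table["flagged"].iloc[0])
        assert np.isnan(table["mean_period_hours"].iloc[0])
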