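"""T-cycle phase normalization and group statistics.

Entrainment experiments run the same panel under zeitgeber cycles of
different total length T (T20, T22, T24, T28 ...).  A clock-driven rhythm
shows systematically earlier phase (as a fraction of the cycle) under
longer T; a masked rhythm simply tracks the zeitgeber, with period equal
to T and cycle-fraction phase constant across T.  To compare phases across
cycle lengths each phase is normalized to a common 24-h cycle
(``phase * 24 / T``) and groups are compared with one-way ANOVA plus
Tukey's HSD post hoc test, summarized as a compact letter display (groups
sharing a letter are not significantly different at the family alpha).

Normalized phases are treated as linear quantities in the ANOVA (the
conventional choice for phases well away from the wrap-around point);
circular ANOVA variants are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import TimeSeriesSet
from .detect import DetectConfig, detect_panel
from .fftnlls import FitConfig, fit_fft_nlls

__all__ = [
    "GroupComparison",
    "normalize_phase_to_24",
    "period_vs_T",
    "compare_groups",
    "compact_letter_display",
]


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD summary across treatment groups."""

    group_labels: list[str]
    group_means: np.ndarray
    group_sems: np.ndarray
    group_ns: np.ndarray
    F_statistic: float
    p_anova: float
    tukey_pairwise: pd.DataFrame  # columns: group1, group2, p_adj, reject
    tukey_letters: dict[str, str]
    alpha: float = 0.05


def normalize_phase_to_24(phase_hours, T_hours: float) -> np.ndarray | float:
    """Rescale a phase measured under a T-cycle onto a 24-h cycle.

    ``phase24 = phase * 24 / T``.  Phases outside ``[0, T)`` are reduced
    modulo T first, with a warning.
    """
    if T_hours <= 0:
        raise ValueError("T_hours must be positive")
    phase = np.asarray(phase_hours, dtype=float)
    if np.any((phase < 0) | (phase >= T_hours)):
        warnings.warn(
            "phase outside [0, T) reduced modulo T before normalization",
            UserWarning,
            stacklevel=2,
        )
        phase = np.mod(phase, T_hours)
    out = phase * 24.0 / T_hours
    return float(out) if out.ndim == 0 else out


def period_vs_T(
    panels: dict[float, TimeSeriesSet],
    detect_cfg: DetectConfig = DetectConfig(),
    fit_cfg: FitConfig = FitConfig(),
    edge_trim_hours: float | None = None,
) -> pd.DataFrame:
    """Mean fitted period per T-cycle panel, over rhythmic ok-status fits.

    Each panel (already preprocessed) is run through rhythmicity calling
    and FFT-NLLS; the returned table has one row per T with the mean
    period, its SEM, the rhythmic count, and a ``flagged`` column set when
    a panel yields no usable replicate.

    ``edge_trim_hours`` excludes that much of each series end from the
    fit (default: half the cycle length T/2), where detrending edge
    effects distort the waveform; rhythmicity is still called on the full
    series.
    """
    rows = []
    for T, panel in sorted(panels.items()):
        calls, _ = detect_panel(panel, detect_cfg)
        flags = dict(zip(calls["replicate_id"], calls["rhythmic"]))
        trim = T / 2 if edge_trim_hours is None else edge_trim_hours
        sub = panel.window(panel.times[0] + trim, panel.times[-1] - trim) if trim > 0 else panel
        periods = []
        for i, rid in enumerate(panel.replicate_ids):
            if not flags.get(rid, False):
                continue
            fit = fit_fft_nlls(
                sub.signals[i],
                sub.times,
                max_components=fit_cfg.max_components,
                circadian_window=fit_cfg.circadian_window,
            )
            if fit.status == "ok":
                periods.append(fit.period_hours)
        n = len(periods)
        rows.append(
            {
                "T_hours": T,
                "mean_period_hours": float(np.mean(periods)) if n else float("nan"),
                "sem_period_hours": float(stats.sem(periods)) if n > 1 else float("nan"),
                "n_rhythmic": n,
                "flagged": n == 0,
            }
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    labels: list[str], sig_diff: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by the standard insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different; ``sig_diff``
    maps unordered label pairs to "significantly different".
    """

    def differ(a: str, b: str) -> bool:
        return sig_diff.get((a, b), sig_diff.get((b, a), False))

    # letter sets: each is a set of mutually non-different groups
    sets: list[set[str]] = [set(labels)]
    for a, b in [(x, y) for i, x in enumerate(labels) for y in labels[i + 1:]]:
        if not differ(a, b):
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            sa, sb = s - {b}, s - {a}
            # insert both reduced sets, then absorb duplicates/subsets
            for cand in (sa, sb):
                if cand and not any(cand <= other for other in sets):
                    sets.append(cand)
    # drop sets absorbed by later insertions
    sets = [s for s in sets if not any(s < other for other in sets)]
    sets.sort(key=lambda s: min(labels.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s, key=labels.index):
            letters[g] += letter
    return letters


def compare_groups(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey HSD all-pairs comparison.

    Requires at least two groups with at least two values each and nonzero
    pooled variance.  The compact letter display is consistent with the
    Tukey pairwise decisions at the family ``alpha``.
    """
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in labels]
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least two groups")
    for g, v in zip(labels, groups):
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("zero pooled variance")

    F, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    codes = np.concatenate([[g] * v.size for g, v in zip(labels, groups)])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)
    tdf = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    pair_df = pd.DataFrame(
        {
            "group1": tdf["group1"].astype(str),
            "group2": tdf["group2"].astype(str),
            "p_adj": tdf["p-adj"].astype(float),
            "reject": tdf["reject"].astype(bool),
        }
    )
    sig = {
        (r.group1, r.group2): bool(r.reject) for r in pair_df.itertuples()
    }
    letters = compact_letter_display(labels, sig)
    return GroupComparison(
        group_labels=labels,
        group_means=np.array([v.mean() for v in groups]),
        group_sems=np.array([stats.sem(v) for v in groups]),
        group_ns=np.array([v.size for v in groups]),
        F_statistic=float(F),
        p_anova=float(p),
        tukey_pairwise=pair_df,
        tukey_letters=letters,
        alpha=alpha,
    )
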