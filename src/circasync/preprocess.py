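"""Smoothing, baseline-and-amplitude (BAMP) detrending, mean normalization.

Raw reporter signals rise continuously because the thalli grow during the
experiment, and oscillation amplitude damps over days.  Both features bias
rhythm statistics, so every series is smoothed with a centered moving
average and BAMP-detrended before rhythmicity testing and fitting: the
moving-average baseline is subtracted and the residual is divided by its
moving-SD amplitude envelope, yielding a dimensionless series with near-zero
local mean and near-unit local amplitude.

Edge policy throughout is window truncation (no padding or reflection):
fabricating data at the series ends would distort the phase estimates that
matter most there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import TimeSeriesSet

__all__ = [
    "DetrendConfig",
    "moving_average",
    "bamp_detrend",
    "normalize_to_mean",
    "preprocess_panel",
    "DegenerateSeriesWarning",
]


class DegenerateSeriesWarning(UserWarning):
    """Raised (as a warning) for inputs with no usable variation."""


@dataclass(frozen=True)
class DetrendConfig:
    """Windows of the smoothing / detrending stack, in hours.

    ``smooth_window_hours`` is the pre-analysis moving average (5 h by
    default), ``baseline_window_hours`` the moving-average baseline and
    ``amplitude_window_hours`` the moving-SD envelope (both one nominal
    cycle, 24 h, by default).  ``amplitude_floor`` is the minimum envelope
    value treated as rhythmic signal; smaller envelopes are clamped so
    near-flat stretches do not blow up after division.
    """

    smooth_window_hours: float = 5.0
    baseline_window_hours: float = 24.0
    amplitude_window_hours: float = 24.0
    amplitude_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("smooth_window_hours", "baseline_window_hours", "amplitude_window_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.amplitude_floor <= 0:
            raise ValueError("amplitude_floor must be positive")


def _window_samples(window_hours: float, dt_hours: float) -> int:
    """Odd sample count spanning the window (symmetric, so linear-phase)."""
    n = max(1, int(round(window_hours / dt_hours)))
    return n if n % 2 == 1 else n + 1


def moving_average(series: np.ndarray, window_hours: float, dt_hours: float) -> np.ndarray:
    """Centered moving average with truncated edges.

    At each point the mean is taken over ``min(window, available)`` samples;
    output length equals input length.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    n = _window_samples(window_hours, dt_hours)
    return (
        pd.Series(series).rolling(window=n, center=True, min_periods=1).mean().to_numpy()
    )


def _baseline(series: np.ndarray, window_hours: float, dt_hours: float) -> np.ndarray:
    """Moving-average baseline with edge-stable local-linear endpoints.

    In the interior this equals the centered moving average (an order-1
    local least-squares fit evaluated at the window center is the window
    mean).  Within half a window of either end the fit uses the nearest
    *full* window instead of a truncated one: truncated cycle-length
    windows track the oscillation itself near the ends, which measurably
    biases downstream period and phase estimates.
    """
    n = min(_window_samples(window_hours, dt_hours), series.size)
    if n < 3:
        return moving_average(series, window_hours, dt_hours)
    return savgol_filter(series, window_length=n, polyorder=1, mode="interp")


def _moving_std(series: np.ndarray, window_hours: float, dt_hours: float) -> np.ndarray:
    """Centered full-window moving SD; edges carry the nearest full window."""
    n = _window_samples(window_hours, dt_hours)
    s = pd.Series(series).rolling(window=n, center=True, min_periods=min(n, series.size)).std()
    return s.bfill().ffill().to_numpy()


def bamp_detrend(
    series: np.ndarray, cfg: DetrendConfig = DetrendConfig(), dt_hours: float = 1.0
) -> np.ndarray:
    """Baseline-and-amplitude detrend one series.

    ``baseline`` is a centered moving average over ``baseline_window_hours``;
    the residual is divided by its centered moving SD over
    ``amplitude_window_hours`` (clamped below at ``amplitude_floor``).
    The result is dimensionless with near-zero local mean.  An all-constant
    input yields an all-zero vector and a :class:`DegenerateSeriesWarning`.
    """
    series = np.asarray(series, dtype=float)
    n_base = _window_samples(cfg.baseline_window_hours, dt_hours)
    if series.size < n_base:
        raise ValueError(
            f"series has {series.size} samples but the baseline window needs {n_base}"
        )
    if np.ptp(series[np.isfinite(series)]) == 0:
        warnings.warn(
            "constant input series: detrended output is all zero",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
        return np.zeros_like(series)
    baseline = _baseline(series, cfg.baseline_window_hours, dt_hours)
    residual = series - baseline
    envelope = _moving_std(residual, cfg.amplitude_window_hours, dt_hours)
    envelope = np.where(np.isnan(envelope), cfg.amplitude_floor, envelope)
    return residual / np.maximum(envelope, cfg.amplitude_floor)


def normalize_to_mean(series: np.ndarray, mode: str = "ratio") -> np.ndarray:
    """Normalize a series to its mean.

    ``ratio`` divides by the mean (presentation convention for raw traces);
    ``centered`` subtracts it (used after BAMP detrending, where the mean is
    already near zero).
    """
    series = np.asarray(series, dtype=float)
    mean = float(np.nanmean(series))
    if mode == "ratio":
        if mean == 0:
            raise ValueError("ratio normalization undefined for zero-mean series")
        return series / mean
    if mode == "centered":
        return series - mean
    raise ValueError(f"unknown mode {mode!r}; expected 'ratio' or 'centered'")


def preprocess_panel(panel: TimeSeriesSet, cfg: DetrendConfig = DetrendConfig()) -> TimeSeriesSet:
    """Smooth then BAMP-detrend every replicate of a panel.

    Smoothing precedes detrending; both use the configured windows.
    """
    dt = panel.dt_hours
    out = np.empty_like(panel.signals)
    for i in range(panel.n_replicates):
        smoothed = moving_average(panel.signals[i], cfg.smooth_window_hours, dt)
        out[i] = bamp_detrend(smoothed, cfg, dt)
    return panel.copy_with(out)
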