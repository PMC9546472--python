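"""Core containers shared by every pipeline stage.

A :class:`TimeSeriesSet` bundles a uniform time grid (hours since entrained
dawn) with a replicate-by-time signal matrix and the light regime the panel
was recorded under.  All analysis operations consume and produce these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["Condition", "LightRegime", "TimeSeriesSet", "UNIFORM_RTOL"]

#: Relative tolerance on grid spacing uniformity.
UNIFORM_RTOL = 1e-9


class Condition(str, Enum):
    """Light condition a panel was recorded under.

    ``FRL``/``FRD`` are free-running (constant light / constant darkness,
    rhythms observed there are circadian); ``ZTC`` is an entraining
    light-dark zeitgeber cycle of total length ``T_hours``.
    """

    FRL = "FRL"
    FRD = "FRD"
    ZTC = "ZTC"


@dataclass(frozen=True)
class LightRegime:
    """Light regime annotation: condition, cycle length and photoperiod.

    Parameters
    ----------
    condition
        ``FRL``, ``FRD`` or ``ZTC``.
    T_hours
        Zeitgeber cycle length in hours (only meaningful under ZTC, but
        carried for all conditions so phase conventions can reference it).
    photoperiod_hours
        Light portion of the cycle; symmetric cycles use ``T_hours / 2``.
    dawn_offset_hours
        Time of the first dawn on the grid; 0 by convention (experiments
        start at entrained dawn).
    """

    condition: Condition = Condition.FRL
    T_hours: float = 24.0
    photoperiod_hours: float = 12.0
    dawn_offset_hours: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.T_hours <= 0:
            raise ValueError(f"T_hours must be positive, got {self.T_hours}")
        if not 0 <= self.photoperiod_hours <= self.T_hours:
            raise ValueError(
                "photoperiod_hours must lie in [0, T_hours]; "
                f"got {self.photoperiod_hours} with T={self.T_hours}"
            )

    @property
    def is_forced(self) -> bool:
        """True when the regime applies zeitgeber forcing (ZTC only)."""
        return self.condition is Condition.ZTC

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "T_hours": self.T_hours,
            "photoperiod_hours": self.photoperiod_hours,
            "dawn_offset_hours": self.dawn_offset_hours,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightRegime":
        return cls(**d)


def _check_uniform(times: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the spacing.

    Raises ``ValueError`` naming the first irregular interval.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D vector with at least 2 points")
    diffs = np.diff(times)
    dup = np.nonzero(diffs == 0)[0]
    if dup.size:
        raise ValueError(f"duplicate time value t={times[dup[0]]:g}")
    if np.any(diffs < 0):
        raise ValueError("times must be strictly increasing")
    dt = diffs[0]
    bad = np.nonzero(np.abs(diffs - dt) > UNIFORM_RTOL * max(abs(dt), 1.0))[0]
    if bad.size:
        i = bad[0]
        raise ValueError(
            "non-uniform time grid: interval "
            f"[{times[i]:g}, {times[i + 1]:g}] has spacing {diffs[i]:g}, "
            f"expected {dt:g}"
        )
    return float(dt)


@dataclass
class TimeSeriesSet:
    """A replicate panel on a uniform hourly grid.

    Attributes
    ----------
    times
        Hours since entrained dawn, strictly increasing, uniform spacing.
    signals
        ``(n_replicates, n_times)`` matrix of signal intensity (arbitrary
        units: DF integrated density, Y(II), NPQ, ...).  NaN marks an
        explicitly flagged missing value.
    replicate_ids
        One label per row of ``signals``.
    regime
        Light regime annotation.
    label
        Free-text signal/treatment label (e.g. ``"DF"``, ``"Y(II)"``).
    """

    times: np.ndarray
    signals: np.ndarray
    replicate_ids: list[str] = field(default_factory=list)
    regime: LightRegime = field(default_factory=LightRegime)
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        _check_uniform(self.times)
        if self.signals.shape[1] != self.times.size:
            raise ValueError(
                f"signals has {self.signals.shape[1]} columns but times has "
                f"{self.times.size} points"
            )
        if not self.replicate_ids:
            self.replicate_ids = [f"rep{i + 1}" for i in range(self.n_replicates)]
        if len(self.replicate_ids) != self.n_replicates:
            raise ValueError("replicate_ids length must match signals rows")
        if np.any(np.isinf(self.signals)):
            raise ValueError("signals must be finite (use NaN for missing)")

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def dt_hours(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration_hours(self) -> float:
        return float(self.times[-1] - self.times[0])

    def copy_with(self, signals: np.ndarray, label: str | None = None) -> "TimeSeriesSet":
        """New panel sharing grid/regime/ids but with replaced signals."""
        return TimeSeriesSet(
            times=self.times.copy(),
            signals=np.asarray(signals, dtype=float),
            replicate_ids=list(self.replicate_ids),
            regime=self.regime,
            label=self.label if label is None else label,
        )

    def window(self, start_hours: float, end_hours: float) -> "TimeSeriesSet":
        """Sub-panel restricted to times in ``[start, end]`` (closed)."""
        eps = UNIFORM_RTOL * max(1.0, abs(end_hours))
        mask = (self.times >= start_hours - eps) & (self.times <= end_hours + eps)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{start_hours}, {end_hours}] contains fewer than 2 samples"
            )
        return TimeSeriesSet(
            times=self.times[mask],
            signals=self.signals[:, mask],
            replicate_ids=list(self.replicate_ids),
            regime=self.regime,
            label=self.label,
        )
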