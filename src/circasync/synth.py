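"""Seeded synthetic delayed-fluorescence / PAM-like panel generator.

The generator emulates the statistical structure the downstream analysis
assumes for photosynthesis reporter time series in *Marchantia polymorpha*
thalli: a damped cosine oscillation per replicate, superposed on a
monotonically increasing growth baseline, with inter-replicate period and
phase heterogeneity (which drives desynchronization under free run),
additive zeitgeber masking under light-dark cycles, and i.i.d. Gaussian
measurement noise.

Per replicate *j* the noiseless model is

    y_j(t) = b0 + b1*t + a_j * 2**(-t/tau_d) * cos(2*pi*(t - phi_j)/T_j)
             + M * L(t)

with ``T_j ~ Normal(mu_T, sd_T)`` and ``phi_j ~ Normal(mu_phi, sd_phi)``
drawn once per replicate, ``L(t)`` the 0/1 light indicator of the regime,
and ``eps_t ~ Normal(0, noise_sd)`` added per sample.  Under an entraining
zeitgeber cycle the oscillation is entrained: ``T_j`` is pinned to the
cycle length and only phase scatter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Condition, LightRegime, TimeSeriesSet, _check_uniform

__all__ = [
    "SimParams",
    "make_light_indicator",
    "simulate_panel",
    "frl_preset",
    "frd_preset",
    "ztc_preset",
    "preset",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic panel model.

    Parameters
    ----------
    n_reps
        Number of replicate thalli.
    duration_hours, dt_hours
        Length and sampling interval of the grid (samples at
        ``0, dt, ..., duration`` inclusive).
    mu_period_hours, sd_period_hours
        Mean and inter-replicate SD of the free-running period (hours).
    mu_phase_hours, sd_phase_hours
        Mean and inter-replicate SD of the cosine peak time after dawn.
    amplitude0
        Initial oscillation amplitude (signal units).
    damping_halflife_hours
        Amplitude halves every this many hours (``inf`` = no damping).
    baseline0, baseline_slope
        Growth baseline intercept and slope (signal units, units/h); thallus
        growth during the experiment produces a continuously rising signal.
    masking_gain
        Additive signal increment per unit light under a zeitgeber cycle.
    noise_sd
        SD of i.i.d. Gaussian measurement noise.
    seed
        Seed for the generator; identical (params, regime, seed) regenerate
        the panel bit-identically.
    """

    n_reps: int = 50
    duration_hours: float = 168.0
    dt_hours: float = 1.0
    mu_period_hours: float = 25.5
    sd_period_hours: float = 1.5
    mu_phase_hours: float = 6.0
    sd_phase_hours: float = 1.0
    amplitude0: float = 10.0
    damping_halflife_hours: float = 60.0
    baseline0: float = 100.0
    baseline_slope: float = 0.5
    masking_gain: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        if self.duration_hours / self.dt_hours < 47:
            raise ValueError("duration/dt must yield at least 48 samples")
        if min(self.sd_period_hours, self.sd_phase_hours, self.noise_sd) < 0:
            raise ValueError("SD parameters must be non-negative")
        if self.amplitude0 < 0:
            raise ValueError("amplitude0 must be non-negative")
        if self.damping_halflife_hours <= 0:
            raise ValueError("damping_halflife_hours must be positive (use inf)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def make_light_indicator(regime: LightRegime, times: np.ndarray) -> np.ndarray:
    """0/1 light indicator ``L(t)`` on a uniform grid.

    Under ZTC the light interval is half-open: ``L = 1`` when
    ``(t - dawn_offset) mod T`` falls in ``[0, photoperiod)``.  FRL is all
    ones and FRD all zeros — the brief measurement light pulses given every
    hour under darkness are not modelled as forcing.
    """
    times = np.asarray(times, dtype=float)
    _check_uniform(times)
    if regime.condition is Condition.FRL:
        return np.ones_like(times)
    if regime.condition is Condition.FRD:
        return np.zeros_like(times)
    t_in_cycle = np.mod(times - regime.dawn_offset_hours, regime.T_hours)
    return (t_in_cycle < regime.photoperiod_hours).astype(float)


def simulate_panel(params: SimParams, regime: LightRegime) -> TimeSeriesSet:
    """Draw one synthetic replicate panel under the given light regime.

    Per-replicate periods and phases are drawn first (one stream), then
    the observation noise, so panels with the same seed but different
    ``noise_sd`` share their underlying oscillators.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_reps
    times = np.arange(0.0, params.duration_hours + params.dt_hours / 2, params.dt_hours)

    periods = rng.normal(params.mu_period_hours, params.sd_period_hours, size=n)
    phases = rng.normal(params.mu_phase_hours, params.sd_phase_hours, size=n)
    if regime.is_forced:
        # entrained: the zeitgeber pins every oscillator to the cycle length
        periods = np.full(n, regime.T_hours)
    periods = np.clip(periods, 1e-6, None)

    decay = np.power(2.0, -times / params.damping_halflife_hours)
    baseline = params.baseline0 + params.baseline_slope * times
    light = make_light_indicator(regime, times)
    forcing = params.masking_gain * light if regime.is_forced else 0.0

    osc = params.amplitude0 * decay[None, :] * np.cos(
        2 * np.pi * (times[None, :] - phases[:, None]) / periods[:, None]
    )
    signals = baseline[None, :] + osc + forcing
    if params.noise_sd > 0:
        signals = signals + rng.normal(0.0, params.noise_sd, size=signals.shape)

    return TimeSeriesSet(
        times=times,
        signals=signals,
        regime=regime,
        label=f"synthetic-{regime.condition.value}",
    )


# ---------------------------------------------------------------------------
# Presets: the study-like conditions each light regime emulates.
# Damping rate and inter-thallus period SD are not published quantities for
# this system; the values below are fixed, documented choices (see the
# methods note), not fitted ones.

_FRL = SimParams(
    n_reps=50,
    duration_hours=168.0,
    dt_hours=1.0,
    mu_period_hours=25.5,
    sd_period_hours=1.5,
    mu_phase_hours=6.0,
    sd_phase_hours=1.0,
    amplitude0=10.0,
    damping_halflife_hours=60.0,
    baseline0=100.0,
    baseline_slope=0.5,
    masking_gain=0.0,
    noise_sd=1.0,
)

# FRD differs from FRL only by noisier, faster-damping rhythms.
_FRD = replace(_FRL, noise_sd=2.0, damping_halflife_hours=48.0)


def frl_preset(seed: int = 0, **overrides) -> tuple[SimParams, LightRegime]:
    """Free-running light: damped ~25.5 h oscillators that desynchronize."""
    params = replace(_FRL, seed=seed, **overrides)
    return params, LightRegime(Condition.FRL, T_hours=24.0, photoperiod_hours=24.0)


def frd_preset(seed: int = 0, **overrides) -> tuple[SimParams, LightRegime]:
    """Free-running darkness: like FRL but noisier and faster-damping."""
    params = replace(_FRD, seed=seed, **overrides)
    return params, LightRegime(Condition.FRD, T_hours=24.0, photoperiod_hours=0.0)


def ztc_preset(seed: int = 0, T_hours: float = 24.0, **overrides) -> tuple[SimParams, LightRegime]:
    """Zeitgeber (T-)cycle: entrained, masked oscillation.

    The entrained peak sits at the middle of the light period (a fixed
    quarter of the cycle), so phase normalized to a 24-h cycle is the same
    fraction of the cycle at every T — the masking null the T-cycle
    comparison is designed to detect.  Forcing is strong and damping
    negligible, reflecting sustained driven rhythms under entrainment.
    """
    kwargs = dict(
        seed=seed,
        mu_period_hours=T_hours,
        sd_period_hours=0.0,
        mu_phase_hours=T_hours / 4.0,
        sd_phase_hours=1.0,
        damping_halflife_hours=float("inf"),
        masking_gain=5.0,
    )
    kwargs.update(overrides)
    params = replace(_FRL, **kwargs)
    regime = LightRegime(Condition.ZTC, T_hours=T_hours, photoperiod_hours=T_hours / 2.0)
    return params, regime


def preset(name: str, seed: int = 0, T_hours: float = 24.0, **overrides) -> tuple[SimParams, LightRegime]:
    """Look up a preset by condition name (``frl`` / ``frd`` / ``ztc``)."""
    name = name.lower()
    if name == "frl":
        return frl_preset(seed, **overrides)
    if name == "frd":
        return frd_preset(seed, **overrides)
    if name == "ztc":
        return ztc_preset(seed, T_hours=T_hours, **overrides)
    raise ValueError(f"unknown preset {name!r}; expected frl, frd or ztc")
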