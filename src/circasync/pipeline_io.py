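"""CSV readers/writers, configuration and the one-command pipeline.

Panels travel as plain CSV: wide layout has a ``time_h`` first column and
one column per replicate; long layout has ``time_h, replicate, value``.
``run_pipeline`` chains preprocess -> detect -> fit -> synchrony in the
stated analysis order and returns a :class:`PipelineReport` whose summary
block is recomputable from the per-replicate table; (input, config, seed)
determine every table exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import LightRegime, TimeSeriesSet
from .detect import DetectConfig, detect_panel
from .fftnlls import FitConfig, circadian_phase, fit_fft_nlls, relative_amplitude_error
from .preprocess import DetrendConfig, preprocess_panel
from .synchrony import sliding_window_sync

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger("circasync")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to re-run a pipeline bit-identically."""

    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    sync_width_hours: float = 48.0
    sync_step_hours: float = 24.0
    sync_start_hours: float = 0.0
    sync_max_components: int = 2
    phase_scale_hours: float = 24.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detrend" in d:
            d["detrend"] = DetrendConfig(**d["detrend"])
        if "detect" in d:
            dd = dict(d["detect"])
            if "period_range" in dd:
                dd["period_range"] = tuple(dd["period_range"])
            d["detect"] = DetectConfig(**dd)
        if "fit" in d:
            fd = dict(d["fit"])
            if "circadian_window" in fd:
                fd["circadian_window"] = tuple(fd["circadian_window"])
            d["fit"] = FitConfig(**fd)
        return cls(**d)


@dataclass
class PipelineReport:
    """Per-replicate calls+fits, synchrony table, summary, config echo."""

    replicates: pd.DataFrame
    synchrony: pd.DataFrame
    summary: dict
    config: PipelineConfig
    version: str = __version__


def _validate_and_interpolate(df_wide: pd.DataFrame) -> pd.DataFrame:
    """Check the time grid and fill isolated single missing samples."""
    times = df_wide["time_h"].to_numpy(dtype=float)
    dups = pd.Series(times).duplicated()
    if dups.any():
        t = times[dups.to_numpy()][0]
        raise ValueError(f"duplicate time value t={t:g}")
    n_filled = 0
    for col in df_wide.columns:
        if col == "time_h":
            continue
        vals = df_wide[col].to_numpy(dtype=float)
        isna = np.isnan(vals)
        if not isna.any():
            continue
        padded = np.concatenate(([False], isna, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for s, e in zip(starts, ends):
            if e - s > 1:
                raise ValueError(
                    f"column {col!r} has {e - s} consecutive missing samples; "
                    "only isolated gaps are interpolated"
                )
        n_filled += int(isna.sum())
        df_wide[col] = pd.Series(vals).interpolate(limit=1, limit_area="inside").to_numpy()
        if np.isnan(df_wide[col]).any():
            raise ValueError(f"column {col!r} has missing samples at the series edge")
    if n_filled:
        log.info("interpolated %d isolated missing values", n_filled)
    return df_wide


def read_timeseries_csv(
    path: str | Path,
    layout: str = "wide",
    regime: LightRegime | None = None,
    label: str = "",
    column_map: dict[str, str] | None = None,
) -> TimeSeriesSet:
    """Read a replicate panel from CSV.

    ``layout='wide'``: first column ``time_h``, remaining columns one per
    replicate.  ``layout='long'``: columns ``time_h, replicate, value``.
    ``column_map`` renames input columns to the expected names first (for
    files with other headers).  Isolated single missing values are linearly
    interpolated (logged); longer gaps are rejected.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if layout == "long":
        required = {"time_h", "replicate", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        df = df.pivot(index="time_h", columns="replicate", values="value").reset_index()
        df.columns.name = None
    if "time_h" not in df.columns:
        raise ValueError("wide layout requires a 'time_h' first column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r}")
    df = _validate_and_interpolate(df)
    rep_cols = [c for c in df.columns if c != "time_h"]
    return TimeSeriesSet(
        times=df["time_h"].to_numpy(dtype=float),
        signals=df[rep_cols].to_numpy(dtype=float).T,
        replicate_ids=[str(c) for c in rep_cols],
        regime=regime or LightRegime(),
        label=label,
    )


def write_timeseries_csv(panel: TimeSeriesSet, path: str | Path) -> None:
    """Write a panel in the wide layout (``time_h`` + one column per replicate)."""
    df = pd.DataFrame({"time_h": panel.times})
    for rid, row in zip(panel.replicate_ids, panel.signals):
        df[rid] = row
    df.to_csv(path, index=False)


def run_pipeline(panel: TimeSeriesSet, config: PipelineConfig = PipelineConfig()) -> PipelineReport:
    """Preprocess, call rhythmicity, fit FFT-NLLS, and compute synchrony.

    Stages run in the analysis order: 5-h moving-average smoothing and
    BAMP detrending, MetaCycle-style rhythmicity calling with the q/period
    filter, whole-series FFT-NLLS per rhythmic replicate, then sliding
    window Kuramoto synchrony over rhythmic replicates.  Randomness (the
    permutation null) flows from ``config.seed``.
    """
    cfg = config
    detect_cfg = dataclasses.replace(cfg.detect, seed=cfg.seed)

    log.info("preprocess: %d replicates, %d samples", panel.n_replicates, panel.n_times)
    try:
        clean = preprocess_panel(panel, cfg.detrend)
    except Exception as e:
        raise RuntimeError(f"preprocess stage failed: {e}") from e

    try:
        calls, fraction = detect_panel(clean, detect_cfg)
    except Exception as e:
        raise RuntimeError(f"detect stage failed: {e}") from e
    n_rhythmic = int(calls["rhythmic"].sum())
    log.info("detect: %d/%d rhythmic (q<%g)", n_rhythmic, len(calls), detect_cfg.q_threshold)

    # whole-series parameter fits exclude half a baseline window at each
    # end, where detrending edge effects distort the waveform
    trim = cfg.detrend.baseline_window_hours / 2
    if clean.duration_hours > 2 * trim + 48:
        fit_panel = clean.window(clean.times[0] + trim, clean.times[-1] - trim)
    else:
        fit_panel = clean

    fit_rows = []
    for i, rid in enumerate(clean.replicate_ids):
        row = {
            "replicate_id": rid,
            "period_hours": np.nan,
            "se_period": np.nan,
            "phase_hours": np.nan,
            "phase_circadian_hours": np.nan,
            "amplitude": np.nan,
            "rae": np.nan,
            "fit_status": "not_fit",
        }
        if bool(calls.loc[calls["replicate_id"] == rid, "rhythmic"].iloc[0]):
            fit = fit_fft_nlls(
                fit_panel.signals[i],
                fit_panel.times,
                max_components=cfg.fit.max_components,
                circadian_window=cfg.fit.circadian_window,
                max_nfev=cfg.fit.max_nfev,
            )
            row["fit_status"] = fit.status
            if fit.status == "ok":
                row.update(
                    period_hours=fit.period_hours,
                    se_period=fit.se_period,
                    phase_hours=fit.phase_hours,
                    phase_circadian_hours=circadian_phase(fit, cfg.phase_scale_hours),
                    amplitude=fit.amplitude,
                    rae=relative_amplitude_error(fit),
                )
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)
    replicates = calls.merge(fits, on="replicate_id")
    n_ok = int((replicates["fit_status"] == "ok").sum())
    log.info("fit: %d/%d rhythmic replicates fit ok", n_ok, n_rhythmic)

    if panel.duration_hours >= cfg.sync_width_hours:
        sync = sliding_window_sync(
            clean,
            calls,
            width_hours=cfg.sync_width_hours,
            step_hours=cfg.sync_step_hours,
            fit_cfg=dataclasses.replace(cfg.fit, max_components=cfg.sync_max_components),
            phase_scale_hours=cfg.phase_scale_hours,
            start_hours=cfg.sync_start_hours,
        )
        sync_df = pd.DataFrame([dataclasses.asdict(s) for s in sync])
    else:
        log.warning("panel shorter than one synchrony window; synchrony table empty")
        sync_df = pd.DataFrame(
            columns=["window_start_hours", "window_end_hours", "n_included", "r",
                     "mean_phase_hours", "mean_rae"]
        )

    ok = replicates[replicates["fit_status"] == "ok"]
    summary = {
        "n": int(len(replicates)),
        "n_rhythmic": n_rhythmic,
        "rhythmic_fraction": fraction,
        "mean_period_hours": float(ok["period_hours"].mean()) if n_ok else None,
        "sem_period_hours": float(ok["period_hours"].sem()) if n_ok > 1 else None,
        "mean_rae": float(ok["rae"].mean()) if n_ok else None,
        "sem_rae": float(ok["rae"].sem()) if n_ok > 1 else None,
        "seed": cfg.seed,
        "version": __version__,
    }
    return PipelineReport(
        replicates=replicates, synchrony=sync_df, summary=summary, config=cfg
    )


def write_report(report: PipelineReport, out_dir: str | Path) -> dict[str, Path]:
    """Write calls.csv, fits.csv, sync.csv, summary.json and config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    call_cols = [
        "replicate_id", "p_ls", "p_jtk", "p_combined", "q",
        "period_ls", "period_jtk", "period_detected_hours", "rhythmic",
    ]
    fit_cols = [
        "replicate_id", "period_hours", "se_period", "phase_hours",
        "phase_circadian_hours", "amplitude", "rae", "fit_status",
    ]
    paths = {
        "calls": out / "calls.csv",
        "fits": out / "fits.csv",
        "sync": out / "sync.csv",
        "summary": out / "summary.json",
        "config": out / "config.yaml",
    }
    report.replicates[call_cols].to_csv(paths["calls"], index=False)
    report.replicates[fit_cols].to_csv(paths["fits"], index=False)
    report.synchrony.to_csv(paths["sync"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(report.config.to_dict(), fh, sort_keys=True)
    return paths
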