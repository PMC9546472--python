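# circasync

Rhythm analysis for circadian reporter time series — built around the
pipeline used to study circadian and diel regulation of photosynthesis in
the liverwort *Marchantia polymorpha*, where delayed chlorophyll
fluorescence (DF) and PAM-derived signals (Y(II), NPQ) from panels of
replicate thalli are recorded hourly for about a week under free-running
light (FRL), free-running darkness (FRD), or entraining zeitgeber
light-dark cycles (ZTC, including non-24-h "T-cycles").

It is aimed at chronobiologists who have a plain table of replicate
intensity traces and want the standard chain of rhythm statistics with a
reproducible, testable implementation:

1. **Preprocessing** — 5-h centered moving average, then
   baseline-and-amplitude (BAMP) detrending: subtract a one-cycle
   moving-average baseline (thallus growth makes the raw signal rise
   continuously) and divide by a one-cycle moving-SD envelope (rhythms damp
   over days).
2. **Rhythmicity calling** — per replicate, a normalized Lomb-Scargle
   periodogram with a seeded permutation null and a JTK_CYCLE rank test
   (Kendall's S against cosine references over a period x lag grid);
   p-values Fisher-combined, Benjamini-Hochberg corrected panel-wide, and
   thresholded with the conventional filter *q* < 0.001 and detected
   period in [18, 34] h.
3. **FFT-NLLS fitting** — FFT-seeded multi-cosine nonlinear least squares
   giving period τ ± SE, amplitude *a*, dawn-referenced phase φ, and the
   relative amplitude error RAE = SE(*a*)/*a* ∈ [0, 1] (0 = robust rhythm,
   1 = indistinguishable from arrhythmic).
4. **Phase synchrony** — replicate phases, circadian-normalized to a 24-h
   circle (φ·24/τ), mapped to angles θ_j; the Kuramoto order parameter
   r·e^{iψ} = N⁻¹ Σ e^{iθ_j} summarizes synchrony per 48-h sliding window
   (step 24 h), with per-window FFT-NLLS refits and per-window exclusion of
   failed fits.
5. **T-cycle and group statistics** — phase normalized to a common 24-h
   cycle (φ·24/T) for comparison across T-cycles, one-way ANOVA with
   Tukey's HSD and a compact letter display. Period and phase tracking T
   across cycle lengths is the diagnostic of zeitgeber *masking*;
   systematically earlier phase under longer T would indicate clock
   control.

A seeded synthetic-panel generator (`circasync.synth`) emulates the data
the pipeline expects — per-replicate damped cosines on a rising growth
baseline, inter-replicate period/phase heterogeneity, additive zeitgeber
masking, Gaussian noise — so the whole stack is testable without any
instrument data.

## Worked example

```python
import circasync as ca

# a free-running panel: 50 replicates, hourly sampling for 7 days,
# mean period 25.5 h with 1.5 h between-replicate SD
params, regime = ca.preset("frl", seed=1)
panel = ca.simulate_panel(params, regime)

report = ca.run_pipeline(panel, ca.PipelineConfig(seed=1))
print(report.summary["rhythmic_fraction"])     # 1.0
print(report.summary["mean_period_hours"])     # 25.3517
print(report.summary["mean_rae"])              # 0.0122
print(report.synchrony[["window_start_hours", "n_included", "r"]])
```

The synchrony table shows the free-running panel desynchronizing as the
heterogeneous periods disperse the phases (this run, seed 1):

```
   window_start_hours  n_included         r
0                 0.0          50  0.951555
1                24.0          50  0.955911
2                48.0          50  0.907948
3                72.0          50  0.763053
4                96.0          50  0.529520
5               120.0          50  0.163443
```

r near 1 in the first 48-h window (phases start clustered) falling to
~0.16 in the last — the desynchronization signature of a free-running
panel. Under the entrained `"ztc"` preset the final-window r stays above
0.95, and fitted periods track the imposed cycle length.

The same stages are available as a CLI:

```sh
circasync simulate --preset frl --n 50 --seed 1 -o panel.csv
circasync pipeline panel.csv -o out/ --seed 1
circasync detect panel.csv -o calls.csv --q 0.001 --n-perm 1000 --seed 7
```

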