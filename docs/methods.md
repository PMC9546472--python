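# Methods

This note records the models, estimators, numerical choices and known
limitations behind `circasync`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## Signal model and the synthetic generator

The pipeline targets panels of replicate reporter traces (delayed
chlorophyll fluorescence, Y(II), NPQ) sampled uniformly — typically every
1–2 h for about seven days starting at entrained dawn (t = 0). The
generator in `circasync.synth` produces panels from the model

    y_j(t) = b0 + b1·t + a_j · 2^(−t/τ_d) · cos(2π(t − φ_j)/T_j)
             + M·L(t) + ε_t

with, per replicate j, period T_j ~ Normal(μ_T, σ_T) and phase
φ_j ~ Normal(μ_φ, σ_φ), and per sample ε_t ~ Normal(0, σ_ε). L(t) is the
0/1 light indicator of the regime: all-ones under constant light (FRL),
all-zeros under constant darkness (FRD; the brief hourly measuring flashes
are not modelled as forcing), and a half-open square wave
[dawn, dawn + photoperiod) under a zeitgeber cycle (ZTC) of total length
T. Under ZTC the oscillation is entrained: T_j is pinned to the cycle
length, phase scatter still applies, and masking enters as the purely
additive, instantaneous term M·L(t) — no phase-resetting dynamics, which
is the simplest model whose fitted period and phase track T.

Parameters that matter, with defaults:

| parameter | default | meaning |
|---|---|---|
| n_reps | 50 | replicate thalli per panel |
| duration, dt | 168 h, 1 h | one week, hourly sampling |
| μ_T, σ_T | 25.5 h, 1.5 h | free-running period mean and inter-replicate SD |
| μ_φ, σ_φ | 6 h, 1 h | peak time after dawn, inter-replicate SD |
| a₀ | 10 | initial amplitude (arbitrary units) |
| τ_d | 60 h (FRL), 48 h (FRD), ∞ (ZTC) | amplitude half-life |
| b₀, b₁ | 100, 0.5/h | growth baseline (raw signals rise continuously) |
| M | 5 (ZTC only) | additive masking gain |
| σ_ε | 1 (FRL/ZTC), 2 (FRD) | measurement noise SD |

The free-running period mean of 25.5 h and the qualitative features —
damping over 4–5 days, a continuously rising baseline, larger scatter in
darkness, sustained driven rhythms under entrainment — reproduce what
this kind of liverwort DF experiment shows. The damping rate and the
inter-thallus period SD are not published quantities; τ_d = 60 h (roughly
2.5-fold decay over a week) and σ_T = 1.5 h (enough that a panel's phases
disperse over ~5 cycles) are fixed design choices, stated here once and
not tuned. The ZTC preset puts the entrained peak at T/4 — the middle of
the light period — so that phase is the same *fraction* of the cycle at
every T; this is the masking null the T-cycle comparison is designed
around.

What the generator deliberately does not emulate: non-sinusoidal
waveforms of real DF (sharp evening peaks), slow drifts in noise
variance, inter-replicate amplitude correlation, phase resetting or
transients after release into free run, and spatial/intercellular
structure within a thallus. Passing the synthetic-panel tests therefore
demonstrates correctness of the estimators under the stated model, not
performance on every pathology of real traces.

## Preprocessing (smoothing and BAMP detrending)

A centered 5-h moving average (truncated at the series ends, no padding)
precedes all statistics. BAMP detrending then removes the growth baseline
and the damping envelope: baseline = centered moving average over one
nominal cycle (24 h default); residual = signal − baseline; envelope =
centered moving SD of the residual over one cycle; output = residual /
max(envelope, floor). The output is dimensionless with near-zero local
mean and near-unit local amplitude.

Edge behavior is where detrending choices bite. A truncated cycle-length
window near the series ends partially tracks the oscillation itself,
which we measured to bias downstream FFT-NLLS periods by 0.3–0.5 h on
noiseless entrained panels. Three choices limit this:

- the *baseline* is computed as an order-1 Savitzky–Golay filter —
  identical to the centered moving average everywhere a full window fits,
  and a linear fit over the nearest full window at the ends (no data are
  fabricated, no reflection);
- the *envelope* extends its nearest full-window value to the ends
  (dividing by a constant cannot shift phase or period);
- *whole-series parameter fits* (the pipeline's period/phase/RAE table
  and the T-cycle analysis) exclude half a baseline window at each end of
  the detrended series. Rhythmicity calls and sliding-window synchrony
  use the full series.

Degenerate inputs: an all-constant series detrends to all zeros and emits
a `DegenerateSeriesWarning` rather than an error, so one dead replicate
cannot abort a panel.

## Rhythmicity calling

Two complementary per-replicate tests, combined:

- **Lomb–Scargle.** Classic Horne–Baliunas normalized periodogram on a
  period grid (0.1-h step) restricted to 18–34 h. Significance of the
  peak power is a seeded permutation test (default 200 shuffles) with the
  add-one correction p = (1 + #{perm ≥ obs})/(1 + n_perm) — exact under
  exchangeability, with a p-value floor of 1/(n_perm+1). The per-frequency
  bases are precomputed so a whole permutation batch is one matrix
  product; agreement of the power profile with `scipy.signal.lombscargle`
  is tested.
- **JTK_CYCLE.** Kendall's S between the series and cosine references on
  a period × peak-lag grid (defaults: periods 18–34 h step 2 h, lags step
  2 h over the full cycle, so anti-phase rhythms are detected
  symmetrically). The null is the tie-corrected normal approximation; for
  short tie-free series (n ≤ 33) the exact enumeration null is used,
  computed from the inversion-count distribution and validated against an
  exhaustive permutation oracle at n = 8. The minimum one-sided p is
  Bonferroni-corrected across the grid.

The two p-values are combined by Fisher's method (−2Σln p against
χ²(2k)) and corrected panel-wide with Benjamini–Hochberg. A replicate is
*rhythmic* iff q < 0.001 (strict) and its detected period — from
whichever test was stronger — lies in the closed interval [18, 34] h.
These thresholds are the field's conventional filter for this assay. An
autoregressive spectral member (the third test in some meta-analytic
callers) is intentionally not included; the two families used here cover
periodogram power and rank concordance.

False-positive behavior is verified directly: on pure-noise panels the
rhythmic fraction at q < 0.001 stays below 1%, and the permutation
p-values are uniform (KS test, acceptance run).

## FFT-NLLS

Period, amplitude and phase come from FFT-seeded multi-cosine nonlinear
least squares: remove a linear trend; seed a cosine at the largest
periodogram peak of the current residual; refit *all* parameters jointly
(offset plus each component's period and cosine/sine coefficients, with
an analytic Jacobian); repeat until four components are reached or the
newest component's amplitude is within one standard error of zero (that
component is dropped). Components are parameterized as
a·cos(ωt) + b·sin(ωt) internally for stability; amplitude, peak-time
phase in [0, τ) and their standard errors come from the linearized
covariance (σ²(JᵀJ)⁻¹ at the optimum) via the delta method.

The *circadian component* is the one with period inside the requested
window (18–34 h; largest amplitude if several). Fits with no such
component, or that fail to converge, carry a non-`ok` status and are
excluded from all downstream means — per window in the synchrony
analysis, not globally. RAE = SE(amplitude)/amplitude of the selected
component, clipped to [0, 1]; this uses the 1-σ linearized error, a
deterministic and testable variant of the joint-confidence-ellipse
definition in the original FFT-NLLS literature (values are comparable but
not bit-identical to that convention).

Phase convention: raw phase is the time of the first fitted peak after
dawn, modulo the period. For cross-replicate comparison it is
circadian-normalized, φ·24/τ — needed so replicates with different
periods share one circle. Whether published phase plots for this assay
use circadian or clock time is not stated anywhere we know of; the
convention here is declared and configurable.

Windowed refits (synchrony) default to at most 2 components: a 48-h
segment spans about two cycles and cannot support the whole-series budget
of four.

## Kuramoto synchrony over sliding windows

Phases of the included replicates map to angles θ_j = 2πφ_j/24 and the
order parameter r·e^{iψ} = N⁻¹Σe^{iθ_j} gives the synchronization index
r ∈ [0, 1] (1 = absolute synchrony) and circular mean phase ψ — never the
arithmetic mean of hours. Windows are [k·step, k·step + width] (48-h
width, 24-h step by default) for as long as they fit; a window start
offset is available because the literature's window enumeration is
ambiguous about whether the first window begins at 0 or one step in. A
window in which no refit succeeds is reported with n = 0 and NaN r, not
dropped.

Free-running panels with σ_T > 0 lose synchrony over days (phases
disperse at a rate set by σ_T), entrained panels do not; the acceptance
run quantifies this as r(last window) < r(first window) for ≥ 45/50
free-running seeds and final-window r ≥ 0.8 for ≥ 45/50 entrained seeds.

## T-cycle analysis and group statistics

For panels entrained to cycle lengths T, the fitted period should track T
under masking, and the phase — normalized to a common 24-h cycle as
φ·24/T — should sit at a constant fraction of the cycle. A clock-driven
rhythm would instead show systematically earlier normalized phase under
longer T. Normalized phases are compared across T (and fitted parameters
across treatment groups) with one-way ANOVA plus Tukey's HSD at family
α = 0.05, summarized as a compact letter display produced by the standard
insert-and-absorb algorithm; letters are checked for consistency with the
pairwise decisions. Phases are treated as linear quantities after
normalization — conventional for phases far from the wrap point, and the
entrained phases here cluster mid-cycle; circular ANOVA variants are out
of scope.

## Determinism and problem sizes

Every stochastic step (simulation, permutation nulls) draws from a
generator seeded at the top level; panel detection spawns one child
stream per replicate so results are independent of evaluation order. The
acceptance script derives all seeds from its `--seed` argument and its
output is bit-reproducible for a given seed. Simulation studies use the
preset panel size (50 replicates, 168 h hourly); seed counts per study
(50 for the synchrony and T-cycle properties, 100 for noisy recovery,
200 panels for false-positive control) were chosen once as the smallest
sizes at which the binomial acceptance margins are meaningful.

## Known limitations

- BAMP here is a declared, configurable algorithm (moving-average
  baseline, moving-SD envelope); published web tools implementing "BAMP"
  do not document their exact smoother, so numerical agreement with them
  is not claimed.
- The LS permutation null assumes exchangeability; applied to strongly
  autocorrelated noise (e.g. heavily pre-smoothed series) it becomes
  anti-conservative. The false-positive guarantee is verified on white
  noise; rhythmicity calling is designed to run on detrended data whose
  residual autocorrelation is modest.
- JTK p-values for long series use the normal approximation with tie
  corrections, standard but approximate in the extreme tail; combined
  with Bonferroni and Fisher they remain conservative in all regimes we
  test.
- RAE and parameter standard errors are linearized (1-σ); for very low
  signal-to-noise fits the linearization underestimates uncertainty, which
  is why non-convergent and windowless fits are excluded rather than
  carried with large errors.
- The masking model is additive and instantaneous; panels generated under
  it cannot exhibit entrainment transients, so tests on ZTC presets say
  nothing about phase-resetting dynamics.
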