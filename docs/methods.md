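# Methods

This note documents the models, estimators, and numerical choices
behind `formin_kinetics`, and what the synthetic-data generators do and
do not emulate.

## Scientific setting

Formins nucleate actin filaments, processively track growing barbed
ends, and can cap ends and bundle filaments. Their biochemistry is
characterized in vitro by three assay families, all covered here:

1. **Bulk pyrene assays** — pyrene-labeled actin reports polymer mass
   as fluorescence over time. Nucleation activity is read from the
   slope of the assembly curve at an early time point (one-eighth
   completion); capping is read from seeded-elongation initial rates.
2. **Single-filament TIRF** — individual filaments are imaged while
   growing from profilin-actin. A processive formin engagement appears
   as a pause (capping), a burst of fast elongation that is dimmer than
   the surrounding filament, and a return to the free rate.
3. **Low-speed co-sedimentation** — bundled filaments pellet at low
   speed; densitometry of pellet vs supernatant bands gives the percent
   of actin bundled per formin dose.

## Bulk quantification

### The t_1/8 nucleation statistic

For each trace, baseline defaults to the first (lightly smoothed)
sample and the plateau to the mean of the final 5% of samples; if the
terminal slope still exceeds 1% of the maximum slope the plateau is
declared indeterminable and an explicit value is required. The time
`t_1/8` at which the smoothed signal crosses
`baseline + (plateau - baseline)/8` is linearly interpolated between
frames, and the assembly slope there is an ordinary-least-squares fit
over a centered 20-s window (the window length is a package choice,
exposed as a parameter; its bias is second order in window x curvature,
so it is negligible on realistically slow traces but material on
artificial fast logistics — see "Numerical choices"). **Nucleation
strength** is the OLS slope of these per-dose slopes against formin
concentration, in a.u./s per nM; the per-trace amplitude (not a shared
actin-alone plateau) normalizes each crossing.

Smoothing is a 5-point Savitzky-Golay filter of order 2 — exact on
locally quadratic signal, so it does not perturb noise-free fixtures
beyond interpolation error.

### Seeded elongation and the tight-binding fit

Initial elongation rates are OLS slopes over the first 90 s,
normalized to the same experiment's actin-alone control. Because the
barbed-end concentration B (~0.1 nM) is comparable to the formin
dose F, occupancy follows the tight-binding (quadratic) form rather
than a hyperbola:

    r(F) = a + b[(B + F + Kd) - sqrt((B + F + Kd)^2 - 4BF)]

with offset `a` (ideally 1 after normalization; deviations beyond 0.1
trigger a QC warning) and scaling constant `b` (per nM; negative for
capping). `r(0) = a` exactly and `r(inf) = a + 2bB`. The discriminant
is clipped at zero against floating-point underflow; a clip deeper
than 1e-8 raises.

The fit is nonlinear least squares over (Kd, a, b) with B fixed.
For fixed Kd the model is linear in (a, b), so each of 13 log-spaced
Kd starts (1e-3 to 1e2 nM) is seeded with its profiled linear
solution before a bounded trust-region refinement; the global best is
kept. Standard errors come from the Jacobian at the optimum. Kd
landing on a box bound — including the degenerate flat-response case —
is flagged as unidentifiable. Tests verify agreement with an
independent exhaustive 200^3 grid search within the grid resolution.

## Single-filament TIRF segmentation

Traces are uniform-cadence length (µm) series, optionally with a tip
intensity channel; 2.5-s frames over 10-min records are the reference
acquisition. Segmentation:

1. **Classification.** Central two-interval slopes (subunits/s, using
   370 subunits/µm) flag candidate pause samples below 5 subunits/s;
   frames with tip intensity below 0.75 of the bright level are dim
   (burst) samples.
2. **Bursts.** Maximal dim runs of at least two frames are fit to a
   line; accepted when the fit slope is positive and R^2 > 0.5.
   Without an intensity channel, fast runs following accepted pauses
   are used instead, with an additional requirement that the burst
   slope exceed 1.5x the free-rate estimate — dimness defines bursts
   in the imaging, and without it an R^2 gate alone would accept
   ordinary free growth.
3. **Pauses.** Runs of flagged samples (single-sample gaps bridged)
   become pauses when their duration reaches 5 s and their fitted
   slope lies in (-10, 5) subunits/s.
4. **Boundary refinement.** Episode endpoints are placed at sub-frame
   resolution: a pause starts where the preceding free-growth line
   crosses the pause plateau level, and ends at the following burst's
   refined start (or the resuming free line); burst endpoints
   apportion the growth of the boundary frame intervals between the
   two regimes using the fitted rates. Detected durations are
   therefore continuous-time estimates, unbiased to well under one
   frame (measured |bias| < 0.4 s on large planted ensembles).
5. **Tiling.** Everything between episodes is free growth; segments
   are emitted as a disjoint cover of the full record.

Events pair each burst with an immediately preceding pause when one
exists; run length is `slope x duration / 370`. Bursts reaching the
end of the record are censored and excluded from run-length statistics
by default. `baseline_return` records whether the following free
segment's rate is within 2 SD of the trace's free-rate population.

### Detection floors and characteristic estimates

Frame-limited detection truncates the event sample, and the summary
reports both raw detected statistics and corrected "characteristic"
estimates of the generating distributions:

- **Pauses** must reach the 5-s rule. For exponential durations,
  memorylessness gives `E[detected] = mean + 5 s`, so
  `pause_char = detected mean - min_pause`.
- **Bursts** must span at least two frames. A burst of duration D
  covers `floor(D/dt + U)` frame instants (U uniform over frame
  phase), so detection requires `D > (2 - U) dt`; averaging over U
  gives an effective floor of 1.5 frame intervals, i.e. 1.5 frames of
  burst growth in run-length units:
  `run_length_char = mean_i(L_i - 1.5 v_i dt / 370)`.
- **Burst rates.** Because faster bursts of the same length span fewer
  frames, detection probability falls as
  `exp(-1.5 v dt / (370 lambda))` with lambda the characteristic run
  length; `burst_rate_char` reweights detected rates by the inverse of
  this probability (for a normal rate distribution the uncorrected
  mean is tilted down by theta sigma^2, about 1.6 subunits/s at the
  reference conditions).

These corrections are derived from the sampling model, not calibrated
to any particular dataset; planted-truth simulations confirm residual
biases of ~3% for all three estimators.

`count_filaments` (the TIRF nucleation test) Otsu-thresholds a field
of view, skeletonizes, and counts connected skeletons at least
`min_length_um` long (pixel count x pixel size as arc length — exact
for straight filaments, a slight underestimate for curved ones).

## Bundling

Percent pelleted is `100 x pellet / (pellet + supernatant)`, valid
because both fractions are loaded in equal volumes; a pellet-vs-total
variant is available for pellet-only gels. Dose curves report per-dose
mean ± SD over replicates (requiring matched dose grids) and flag
non-monotonicity beyond two pooled standard errors.

## Gated statistics

Group comparisons follow a fixed decision tree: trim
`floor(0.025 n)` values per tail when n > 20 (strictly exceeds; note
n = 21 trims nothing because floor(0.525) = 0); Shapiro-Wilk on each
group at 0.05 (the gate level is a parameter; the convention is
silent); both normal → Student's unpaired two-sample t-test, else
Mann-Whitney U; pairwise alpha is Bonferroni-corrected by the
caller-supplied family size. Three or more groups use one-way ANOVA
with post hoc Tukey HSD, whose adjusted p-values already control the
family-wise rate (no additional Bonferroni on that path). Simulated
null calibration: type-I error 5.6% at nominal 5% (n = 30 per group,
2000 replicates), Tukey any-pair false-positive rate below 7%.

## Synthetic-data generators

All generators are pure functions of parameters and a seed.

- **Bulk ODE** (`simulate_bulk_assembly`): a deliberately minimal
  model — spontaneous trinucleus formation `k C^3`, formin-assisted
  nucleation `k' C^2 F`, and elongation `k+ C - k-` partitioned
  between free and formin-bound ends (bound fraction from the
  end-binding Kd; bound ends elongate at `capped_elong_factor`).
  Integrated with fixed-step RK4 at dt = 0.1 s; monomer + polymer +
  3x nuclei is conserved to rounding. The dose-dependent plateau
  depression is modeled as a multiplicative fluorescence artifact
  `1 - c x bound_fraction` (the phenomenon reflects capping, not
  polymer loss). This generator produces realistically shaped trace
  families; it is not used for parameter-recovery targets.
- **Logistic fixtures** (`simulate_bulk_from_slopes`): deterministic
  curves `P / (1 + exp(-k(t - t0)))` with `k = 64 s / (7P)`, so the
  analytic derivative at one-eighth completion equals the requested
  slope exactly (`dF/dt = kF(1 - F/P)` evaluates to `7kP/64` at
  `F = P/8`). `t0` places the crossing five time-constants into the
  trace so the initial signal is negligible; baseline and plateau are
  recorded on the trace. These are the ground truth for
  nucleation-strength recovery.
- **Seeded elongation**: `baseline + v0 r(F) tau (1 - e^(-t/tau))`,
  whose initial slope is exactly `v0 r(F)` with r from the quadratic
  model. The depletion timescale tau defaults to 4000 s so that the
  90-s regression window sits within the initial linear regime —
  the assay's own design assumption; with per-experiment
  normalization the choice cancels out of the Kd fit entirely.
- **Filament traces**: renewal process — free growth at `v_free`
  (default 10 subunits/s), formin capture at exponential waiting
  times (`k_attach` = 0.01 /s, reproducing the observed ~4-5 events
  per filament per 10 min), pause ~ Exp(12 s), burst length ~
  Exp(1.10 µm) at a rate drawn per event from a truncated normal
  (39 ± 13 subunits/s, floored at the free rate — measurement noise
  alone cannot produce the observed rate spread at 2.5-s sampling).
  Lengths are sampled at the frame interval with additive Gaussian
  noise (default 0.03 µm, sub-pixel tracking accuracy at 0.16 µm
  pixels); the tip-intensity channel is `dim_factor` (default 0.5,
  phenomenological — the physical origin of dim segments is not
  modeled) during bursts.
- **Kymographs**: per-frame intensity profiles with burst-grown
  stretches at the dim level, Gaussian PSF blur, additive noise;
  16-bit TIFF-compatible. A simple farthest-edge tracker (threshold
  at 30% of amplitude, below the dim level so a dim tip is still
  tracked) inverts zero-noise renders to within one pixel.
- **Gels**: per-lane totals scatter lognormally (CV `noise_cv`); the
  pellet share is the true fraction plus zero-mean densitometry
  noise, so expected shares equal the truth and the zero-noise round
  trip is exact.

### What the generators do not emulate

No mechanistic FH1/profilin transfer kinetics, no filament buckling or
Brownian dynamics, no photobleaching/photophysics, no tracking
failures, filament crossings, or drift, and no annealing/severing.
Passing recovery tests therefore demonstrates that the estimators are
correct for data obeying the stated statistical structure
(exponential waiting times, piecewise-linear growth, Gaussian length
noise), not that they are robust to every imaging pathology of real
TIRF data.

## Numerical choices and degenerate inputs

- Subunit/length conversion fixed at 370 subunits/µm.
- Slope-at-t_1/8 window default 20 s; OLS window bias is
  `~0.034 (k w)^2` relative for a logistic, immaterial for k <= 0.035
  (the fixture regime) but tens of percent for a k = 1 curve — the
  identity `7kP/64` is only measurable there with a ~2-s window.
- Pause-slope gate uses central slopes for discrimination (noise SD
  per interval at default settings is ~6 subunits/s; averaging two
  intervals halves it) but raw interval growths for boundary
  placement.
- Traces shorter than 8 samples, non-uniform sampling (>1% cadence
  jitter), non-increasing time bases, negative concentrations, and
  fractions outside [0, 1] are rejected with named errors; flat bulk
  traces raise "incomplete reaction"; zero detected events yield an
  explicit empty summary rather than NaN arithmetic downstream.
- All stochastic entry points take integer seeds; ensembles spawn
  per-trace child seeds so trace counts do not perturb each other's
  streams.

## Problem sizes

Recovery checks use ensembles of 50-150 simulated filaments (several
hundred planted events), dilution series of 10 doses, 2000-replicate
null calibrations for the gated statistics, and 200-point-per-axis
grids for the fit oracle; these sizes put Monte-Carlo error well below
the tolerances tested while keeping the whole suite in tens of
seconds.

## Known limitations

- The paper-facing value of the nucleation statistic depends on each
  trace reaching a measurable plateau or carrying an explicit one.
- Run-length statistics below roughly half a frame of burst growth
  (~0.25 µm at reference conditions) are unobservable; the
  characteristic estimates correct the mean but cannot restore the
  censored lower tail.
- The slope-only (no-intensity) burst path is cruder than the
  intensity path: boundaries are placed at half-frame offsets and the
  rate-factor gate rejects bursts slower than 1.5x the free rate.
- `compare_many` trims each group independently before the ANOVA;
  with heavy ties the Shapiro-Wilk gate (pairwise path) can be
  unstable for near-constant samples.
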