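# formin-kinetics

Quantification pipeline for in vitro actin-assembly biochemistry of
formins: bulk pyrene kinetics, barbed-end affinity by tight-binding
fits, single-filament TIRF pause/burst analysis, low-speed
co-sedimentation bundling, and the gated statistics used to compare
constructs — together with synthetic-data generators that plant known
ground truth for every assay class, so the whole pipeline is testable
end to end without any experimental download.

It is written for quantitative biochemists analyzing plate-reader
fluorescence traces, TIRF filament tracks, and gel densitometry for
actin nucleators such as FHOD3, and for anyone who wants honest,
resolution-aware estimators of formin processivity parameters.

## What it computes

**Nucleation strength.** For each assembly trace the time to one-eighth
completion, t_1/8, is found and the local slope there measured; the
OLS slope of those slopes against formin dose (a.u./s per nM) is the
construct's specific nucleation activity.

**Barbed-end affinity.** Seeded-elongation initial rates (90-s
regression, normalized to actin alone) are fit to the tight-binding
(quadratic) occupancy model, required because barbed ends (~0.1 nM)
and formin are comparably dilute:

    r(F) = a + b[(B + F + K_d) − sqrt((B + F + K_d)² − 4BF)]

with B fixed and (K_d, a, b) fit by multi-start nonlinear least
squares.

**TIRF events.** Length-vs-time traces are segmented into free growth,
pauses (≥ 5 s, slope within −10 and 5 subunits/s) and bursts (dim,
fast, line-fit R² > 0.5); per-event pause durations, burst rates, and
run lengths are summarized with detection-floor-corrected
"characteristic" estimates of the underlying exponential means
(see `docs/methods.md`).

**Bundling.** Percent actin pelleted per lane,
100·pellet/(pellet+supernatant), with replicate mean ± SD dose curves.

**Statistics.** The gated comparison tree: 2.5%-per-tail trimming for
n > 20, Shapiro-Wilk normality gate, Student's t vs Mann-Whitney U,
Bonferroni-corrected alpha; ANOVA + Tukey HSD for ≥ 3 groups.

## Worked example

Run the built-in demonstration pipeline (simulates every assay class
at reference conditions, quantifies each, and writes results plus a
reproducibility manifest):

```bash
formin-kinetics run --out demo_results
```

Key numbers from the printed results (seed 0):

```text
affinity:    kd_nM = 0.023, a_offset = 1.000, b_scale_per_nM = -4.5
nucleation:  strength = 0.3218 a.u./s per nM (intercept 0.084 a.u./s)
tirf:        n_events = 44 from 12 filaments
             burst_rate_char = 41.3 subunits/s (raw mean 40.2 ± 10.5)
             run_length_char = 1.17 µm (raw mean 1.58)
             pause_char      = 14.5 s  (raw mean 19.5)
bundling:    82.3 ± 0.1 % pelleted at 60 nM (5.0 % at 0 nM)
```

Reading these: the seeded-elongation series was generated at
K_d = 0.023 nM and the fit returns it exactly; the logistic
nucleation fixtures were built on a 0.32 a.u./s-per-nM dose line and
the t_1/8 pipeline recovers 0.322; the 12 simulated filaments carried
bursts at 39 ± 13 subunits/s with exponential run lengths (mean
1.10 µm) and pauses (mean 12 s) — the raw detected means are inflated
by the 2.5-s frame resolution floor, and the `*_char` estimates
correct for it (at this small n they sit within ~2 SEM of the
generating values; larger ensembles converge tightly). The bundling
curve was planted with 81.7% pelleted at 60 nM and 5% densitometry
noise.

The same operations are available as a library:

```python
import numpy as np
import formin_kinetics as fk

traces = fk.simulate_seeded_elongation(
    kd=0.47, a_offset=1.0, b_scale=-4.5, barbed_ends=0.1,
    formin_series=[0.0, *0.47 * np.geomspace(0.1, 100, 9)])
rates = [(t.formin_nM, fk.initial_rate(t)) for t in traces]
control = dict(rates)[0.0]
fit = fk.fit_barbed_end_affinity(fk.normalize_rates(rates, control),
                                 barbed_ends_nM=0.1)
print(fit.kd_nM)   # 0.47
```

The fitting and segmentation surfaces are sklearn-style estimators
(`BarbedEndAffinityFit`, `NucleationStrength`, `TraceSegmenter`) with
`fit`/`transform`, `get_params`, and trailing-underscore attributes.

## Layout

```
src/formin_kinetics/
  simulate.py    synthetic-data generators (all three assay classes)
  pyrene.py      t_1/8 statistic, initial rates, quadratic Kd fit
  tirf.py        trace segmentation, events, summaries, filament counting
  bundling.py    co-sedimentation quantification
  stats.py       gated group comparisons
  io.py          CSV/JSON readers and writers
  pipeline.py    manifest-driven runs
  cli.py         `formin-kinetics` command-line interface
docs/methods.md  models, estimators, corrections, limitations
```
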