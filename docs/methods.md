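# Methods

This note documents the models, conventions and numerical choices behind
`avmod`, and what the simulator-based validation does and does not show
about real recordings.

## Data model and windows

Time zero is the onset of the 500-ms static first frame; the dynamic
movie (and sound, when present) starts at `movie_onset` (0.5 s by
default) and lasts `D` seconds, which varies between stimuli. Three
modalities are analyzed: audiovisual (`AV`), visual-only (`V`, silent
movie) and auditory-only (`A`, sound with a fixation marker only).

* **Response window**: `[movie_onset, movie_onset + D + 0.1)` s — the
  dynamic epoch plus a 100-ms tail that captures offset activity. The
  same window is applied to all three modalities (the sound and movie
  onsets are aligned, so no modality-specific shift is warranted).
* **Baseline window**: `[-0.3, 0)` s before the still frame.
* **Still-frame window**: `[0, movie_onset)`, used only for the
  onset-transient scatter analysis; the choice of this window is a
  package convention.
* All windows are **half-open** — a spike exactly at the end time never
  counts, one exactly at the start always does. The inclusive/exclusive
  convention is not dictated by the analysis itself; half-open intervals
  were chosen because they tile the time axis without double counting.
* Rates are spikes per second: window count divided by window length,
  and `rate_bs` subtracts the same trial's baseline rate. Negative
  baseline-subtracted rates are retained everywhere except inside the
  index formulas (below).
* The spike-density function (Gaussian kernel, default SD 20 ms on a
  1-ms grid) is provided for display only and feeds no statistic.

## Factorial classification

Each stimulus presentation contributes one observation to a 2×2 design:
auditory presence × visual presence. `AV`, `V` and `A` response-window
rates fill three cells; the fourth, stimulus-absent cell is populated by
the **per-trial baseline-window rates of all trials** of that stimulus.
This uses only data the paradigm provides, at the cost of an unbalanced
design (the baseline cell has three times the trials and a shorter
window, hence higher variance); the engine therefore computes
Type-III-equivalent F-tests by effect (sum-to-zero) coding and
full-versus-reduced residual-sum-of-squares comparison, which is exact
for unbalanced cell counts. Degenerate inputs are handled explicitly:
any empty cell raises a design error; identical observations report
F = 0, p = 1; a nonzero effect over zero residual variance reports
F = +∞, p = 0.

Classification precedence: a significant interaction ⇒ *non-linear
multisensory* (even if both mains are also significant — the observed
category proportions are disjoint only under this precedence); otherwise
both mains ⇒ *linear multisensory*; otherwise a single main effect ⇒
*visual* or *auditory*; otherwise *unresponsive*. Defaults are
α = 0.01 for both the combined-stimuli and per-stimulus analyses; the
per-stimulus threshold is configurable and an optional Bonferroni
correction across stimuli is provided but off by default, matching
common practice of treating each stimulus as a separate planned test.
Stimuli with fewer than 5 trials in any modality are skipped with a
logged warning. A neuron is *responsive* (retained for population
summaries) if any term of any per-stimulus or combined ANOVA is
significant.

## Indices

* **Index of modulation** `(AV − V)/(AV + V)` on baseline-subtracted
  mean response rates per neuron × stimulus. Negative means are clipped
  to zero for the index only, preserving the [−1, 1] range; if the
  clipped sum is zero the index is undefined (NaN) and excluded from
  population medians. The per-neuron *collapsed* index is the arithmetic
  mean of the defined per-stimulus indices (not the index of pooled
  rates). Clipping can be disabled in `RunConfig`.
* **Face-selectivity index** `(face − nonface)/(face + nonface)` with
  the strict criterion `|FSI| > 1/3` — a 2:1 response ratio (FSI exactly
  1/3) is *not* face-selective. The population Spearman correlation of
  modulation against FSI is reported for both the signed index and its
  magnitude, since either convention is defensible.

## Statistical engines

All engines are implemented from the underlying algebra; scipy supplies
only reference distributions (F, t, studentized range).

* One-sample *t*: standard formula, two-sided, df = n − 1.
* Spearman: Pearson correlation of mid-ranks (average ranks for ties),
  p by the t-approximation with n − 2 df.
* Tukey–Kramer: `q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` with
  pooled within-group MSE; the family-wise adjusted p uses scipy's
  studentized-range distribution (numerical integration, no table
  lookups), validated in the test suite against a 10⁶-draw Monte-Carlo
  oracle to within 0.005.
* Mixed model: Gaussian random-intercept-per-neuron model with fixed
  effects {intercept, auditory presence, visual presence, patch,
  patch×auditory}, fit by maximum likelihood. For a fixed variance ratio
  θ = σ²_neuron/σ²_resid the GLS estimate and the profiled σ² are
  closed-form (per-group Woodbury inversion of the compound-symmetric
  covariance), leaving a one-dimensional optimization over log θ
  (bounded search, explicit comparison with the θ = 0 boundary).
  Inference is Wald t with residual df = n_rows − n_fixed; Satterthwaite
  df are not attempted. The default observation unit is the per-neuron
  mean rate of each condition (AV/V/A response rates plus the baseline
  rate as the stimulus-absent cell, averaged across stimuli);
  per-stimulus condition means are available via
  `RunConfig.mixed_model_unit` since the appropriate unit depends on how
  many distinct stimulus means one wishes to weight. Patch labels are
  supplied through an optional `patches.csv` sidecar because they
  describe neurons, not trials.

## Simulator

The generator plants neural consequences, not stimuli. Intensity for
one (neuron, stimulus, modality):

```
lambda(t) = b                                        t < 0
            b + A_tr * exp(-t / tau)   (AV, V only)  0 <= t < movie_onset
            b + drive                                movie epoch
            b                                        after the movie
```

with `drive = rv` (V), `ra` (A), and `g*rv + ra` (AV); bimodal
sub-variants override the AV drive to equal one unimodal drive. The
auditory-only condition has no still-frame transient (no face on
screen). The interaction is a multiplicative gain on the visual drive
because that reproduces the dominant observed phenotype — no response to
sound alone yet an elevated audiovisual response — and gives the
closed-form expected index `(g − 1)/(g + 1)` used by the recovery tests
(the movie/window dilution factor cancels in the ratio). Spikes are
drawn by thinning a homogeneous Poisson process at the intensity
maximum; the epoch runs from −0.5 s to 300 ms past the response window
so edge effects never truncate analysis windows. Everything is
deterministic given the seed (per-neuron substreams from a
`SeedSequence`).

Defaults are the study conditions: 15 stimuli (five vocalization call
types cycled, durations uniform on 1–3 s), 30 repetitions per stimulus
per modality (within the experimental 20–40 range), a 119-neuron
strongly modulated preset (55% non-linear, 15% linear, 5% auditory, 25%
visual; within non-linear: 70% enhancement, 20% suppression, 10%
bimodal) and a 55-neuron unmodulated preset (90% visual, 10%
unresponsive). Firing-rate magnitudes are not constrained by published
values; baseline 5 sp/s, visual drives 5–30 sp/s, auditory drives
5–15 sp/s, gains 1.5–2.5 (enhancement) and 0.2–0.6 (suppression) were
chosen once as physiologically plausible rates giving realistic
single-trial signal-to-noise, and are exposed in `SimConfig`. An
optional log-normal per-trial gain (off by default) adds super-Poisson
variability for calibration stress tests.

What passing recovery tests show: the pipeline correctly inverts data
generated under its own assumptions at realistic rates. What they do not
show: robustness to features of real recordings the generator omits —
non-Poisson spiking statistics, rate drift and adaptation across
trials, correlated noise, latency jitter, stimulus-locked temporal
structure within the movie, and eye-movement-dependent gain.

## Determinism and outputs

`analyze` is deterministic given (dataset, config); all result tables
are byte-identical across reruns. The run manifest records config,
input/output checksums, package version and row counts; its timestamps
are the only non-deterministic output bytes. Validation errors name the
offending file and 1-based data row.

## Problem sizes used in validation

The test suite validates engines on 100 randomized small instances per
oracle, calibrates type-I error with 10,000 null ANOVA replicates,
recovers a planted mixture with 200 neurons × 15 stimuli × 30
repetitions, and measures mixed-model CI coverage over 200 simulated
datasets of 50 neurons; the acceptance script uses the 119/55-neuron
presets. These sizes give Monte-Carlo confidence intervals comfortably
tighter than the tolerances they are checked against.
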