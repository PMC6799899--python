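# Methods

`gistate` analyses multi-electrode gastrointestinal (GI) myoelectric
recordings — electrogastrograms recorded from serosal "paddle" electrodes —
and detects the physiological state of the stomach around an emetic
challenge. This note documents the models, the numerical choices, and what
the synthetic data generator does and does not emulate.

## Signal model and preprocessing

The gastric slow wave is a quasi-sinusoidal oscillation near 9–10
cycles/min (cpm) in ferret, riding on broadband background activity, contact
noise, and low-frequency drift. Each paddle carries four contacts; the paddle
signal is the pointwise mean of its contacts, which preserves the shared
myoelectric component and reduces independent contact-noise variance by
roughly 1/4. Optionally, the difference of two paddle signals (a bipolar
montage, `bipolar:A-B`) rejects drift and any other component common to both
sites; for k paddles there are k(k−1)/2 such pairs.

The filter cascade is: 4th-order Butterworth low-pass at 2.5 Hz (150 cpm) at
the native rate, downsample to 10 Hz, then 2nd-order Butterworth low-pass at
0.3 Hz (18 cpm). Both stages are applied zero-phase (forward–backward,
`sosfiltfilt`): the analysis is post hoc, and zero-phase filtering keeps
window boundaries aligned with the event timeline. Note that a zero-phase
stage contributes |H(f)|², so the in-band gain at 9.5 cpm is ≈0.93 rather
than the single-pass 0.96; all band *percentages* are unaffected. When the
native-to-target rate ratio is an integer the downsample is plain decimation
(the 2.5 Hz stage is the anti-alias filter for the 5 Hz target Nyquist);
otherwise polyphase resampling is used.

High-amplitude transients (10–20 s, far above physiological amplitude) are
blanked before filtering: samples deviating from the trace median by more
than k·MAD (default k = 8) flag an artifact, and the ±30 s window around each
flagged run is replaced by the trace median — a 1-min blank, median-valued to
avoid step edges ringing through the filters. Detection parameters are
configurable and explicit artifact events are honoured the same way. Blanked
intervals are recorded, never deleted, so timing is preserved; 1-min analysis
windows overlapping a blank are excluded from feature tables rather than
half-filtered. The threshold and the centred (rather than
segment-boundary-aligned) blank are package choices; only the 1-min extent of
the blank is inherited from the published analysis.

The hardware acquisition chain's 0.1 Hz (6 cpm) high-pass character belongs
to the recording device, so it lives in the synthetic generator, not in the
processing cascade.

## Spectra, dominant frequency, bands

Each trace is tiled into non-overlapping 60 s windows (600 samples at
10 Hz). A window is mean-removed and zero-padded to 2000 samples so the DFT
bin spacing is 10/2000 Hz = 0.3 cpm — the minimal construction that puts the
spectrum on the published 0.3 cpm grid. The window is rectangular (no taper)
by default; padding interpolates the spectrum, so an on-grid tone still leaks
into neighbouring bins through the Dirichlet kernel — tests that need exact
single-bin behaviour use constructed line spectra.

Per window: the dominant frequency (DF) is the bin with maximal power in
0–15 cpm; the total power is summed over 6–15 cpm (30 bins, half-open
[6, 15)); band percentages are taken relative to the DF — bradygastric
(DF−3, DF−1), normogastric (DF±1), tachygastric (DF+1, DF+3) — each band a
half-open [lo, hi) interval on bin centres so shared edges are counted once.
A window whose DF ≤ 3 cpm has no defined bradygastric band; its percentages
are NaN sentinels and such windows are dropped at classifier entry. Whether
band edges follow each window's own DF (default, used for features) or a
fixed session-level DF (used for figure-style summaries) is configurable.

A session-level DF is *validated* statistically: a one-way ANOVA across
frequency bins (windows as replicates) asks whether any bins differ, then the
global peak of the mean spectrum is compared against each rival local peak
(strict local maxima on the grid) with simultaneous one-sided contrasts. The
contrast adjustment is single-step max-t over the empirical contrast
correlation (multivariate-t box probabilities), with Bonferroni as a
numerical fallback; the DF is validated iff the ANOVA and every contrast
reject at α = 0.05. Treating windows as independent replicates is an
idealisation — adjacent 1-min windows of a slow oscillation are correlated —
so the ANOVA p-values are anti-conservative in absolute terms; the decision
is used as a screening criterion, as in the original analysis, not as a
calibrated test.

## Features and labels

Seven features per window: P_brady, P_norm, P_tachy (band percentages), DF,
DP (power in the single 0.3 cpm bin at the DF), LL (line length, Σ|Δx|, the
raw first difference — the 1/fs factor of a true derivative is a constant
that median normalization cancels), and ZX (zero crossings of the
mean-removed window; zeros carry the previous nonzero sign; without mean
removal a near-DC offset would pin ZX at 0). Each feature column is divided
by its median computed per signal source over all of that source's windows,
so every column has median 1; a zero median falls back to the median absolute
value. Subtractive centring and baseline-only medians are config options.

Emetine-trial labels: windows fully before the infusion are `baseline`; the
infusion-to-first-retch interval is halved into `early` and `late`. A window
must be fully contained in a state interval — boundary-straddling windows are
dropped, keeping the early and late durations exactly equal. Classes are then
randomly undersampled to the smallest class count (the usable windows per
state are limited by the shortest state), giving the uniform prior that makes
the chance level 1/k. A session with under one minute of baseline simply runs
as a two-state (early/late) problem.

## Classification

Per signal source: 20% of the balanced windows are held out, stratified with
an *equal count per class* (a rounded total holdout would force a small class
imbalance whose anti-correlated training set biases permutation-chance
estimates visibly at these sample sizes). On the training 80%, greedy forward
feature selection maximises 5-fold stratified grid-search CV accuracy: kNN
(Euclidean, neighbours 1–10, capped at the fold size) and RBF-SVM
(γ ∈ {10⁻³, 10⁻⁴}, C ∈ {1, 10, 100, 1000}, one-vs-one for 3 classes).
Selection stops when no added feature improves CV accuracy; ties prefer the
smaller model (fewer neighbours; smaller C, then larger γ) and the
lower-indexed feature. The ten best subsets encountered are recorded. An
exhaustive subset search (≤12 features) is provided as a test oracle for the
greedy procedure.

Test metrics come from the confusion matrix: accuracy is trace/total;
per-class precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
TN/(TN+FP) from one-vs-rest counts. The reported accuracy ± 95% CI is the
mean ± 1.96·SE over repeated resampling (default 20 repeats of fresh
undersampling, split, selection, fit, test; every repeat's seed is stored).
The chance level reruns the whole procedure on label permutations (feature
selection off by default in the null — permuted labels carry no signal for
selection to find, and the null is then affordable at hundreds of
scrambles). Scrambling happens before the holdout, i.e. the permutation is
over the full balanced table. Per-subject reports are produced per source;
both algorithm families are run and the better one reported, and a
best-source summary mirrors the per-animal optimum.

## Synthetic sessions

The generator emulates what the pipeline measures, not gastric biophysics:

* slow wave: sinusoid at the state's instantaneous frequency with
  a mean-1 Ornstein–Uhlenbeck amplitude envelope (relaxation 60 s, stationary
  SD 0.25) — window-to-window amplitude variability without phase breaks;
* background: Gaussian noise low-passed at 0.4 Hz (24 cpm), SD 0.35 mV,
  independent per paddle; shared low-frequency drift (SD 0.2 mV, <0.02 Hz)
  common to all contacts; independent 0.05 mV white noise per contact;
  a causal one-pole 0.1 Hz high-pass models the acquisition hardware;
* defaults: 4 paddles × 4 contacts at 250 samples/s (the cascade uses nothing
  above 2.5 Hz, so hardware-rate emulation would be pure cost), slow-wave
  amplitude 0.3 mV, baseline DF 9.5 cpm. These give baseline P_norm near 60%
  and a validated DF in essentially every baseline session, matching the
  reported baseline phenomenology (DF 9.53 ± 0.67 cpm, P_norm 57 ± 14%);
* timeline: 10 min baseline, infusion, first retch after a truncated-normal
  latency (29.5 ± 2.9 min acute defaults; 23.7 ± 2.5 chronic preset;
  floor 5 min), 2 min tail;
* state effects: slow-wave power ×0.8 (early) and ×0.6 (late) — the gradual
  normogastric power decline — and DF ×1.05 (early), ×1.10 (late), a
  gradualised version of the reported post-infusion DF increases (up to 30%
  near the pacemaker). A power-only early effect is statistically invisible
  at these window counts and noise levels, which contradicts the observed
  detectability of the early state; the small early DF shift restores it.
  All effects are config fields; setting them to neutral values sends
  classifier accuracy to chance;
* artifacts: Poisson (1/hour), 10–20 s tapered boxcars at 25× the slow-wave
  amplitude, injected into every channel;
* cohorts: per-subject jitter of DF (SD 0.5 cpm) and amplitude (lognormal,
  ~20%), with all draws recorded in a ground-truth manifest.

What the generator does **not** emulate: spatial propagation across paddles
(each paddle's slow wave has independent phase), non-stationary coupling,
respiratory/cardiac contamination, electrode impedance changes, or any
specific animal's waveform. Passing tests therefore demonstrate that the
pipeline recovers the structures it assumes — a dominant spectral peak,
DF-relative band shifts, state-dependent spectra — not that those structures
exhaust real recordings.

## Problem sizes and determinism

Default study sizes used by the analysis scripts: one session ≈ 42 min
(≈10/15/15 baseline/early/late windows before balancing); chance levels from
300 label scrambles; accuracy CIs from 10–20 resampling repeats; parameter
recovery over 100 seeded 10-min baseline sessions. Every stochastic step
takes an explicit seed; derived child seeds are drawn below 2³¹ and recorded
in reports, so any repeat is individually reproducible.

## Known limitations

* The ANOVA replicate structure ignores temporal correlation (above).
* At ~30 balanced windows per session, test sets are small (6 windows);
  single-split accuracies are coarse, which is why reported accuracies are
  repeated-resampling means.
* The permutation chance at these sizes has Monte-Carlo SE ≈ 1–2 percentage
  points per 100–300 scrambles; quoted chance levels are means, not exact
  33.3/50.
* Feature selection inside each resampling repeat can select different
  subsets across repeats; reports show the subset of the best CV repeat.
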