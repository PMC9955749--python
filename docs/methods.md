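# Methods

## Data model and conventions

An RR series is an ordered sequence of beat-to-beat intervals in
milliseconds. Beat *i*'s time is the **end** of interval *i*
(`beat_time[i] = cumsum(rr[:i+1]) / 1000`, seconds from the first beat);
this single convention fixes the abscissa for the unevenly sampled
periodogram and for epoch membership, and is used everywhere. Epoch windows
are half-open `[start, end)` on beat time, so adjacent 5-min epochs never
share a beat.

## Cleaning

Two rules, evaluated per beat in one forward pass, outlier before ectopic:

* outlier: interval outside `[280, 1500]` ms;
* ectopic: relative change versus the reference interval above 20%.

The reference is the *last accepted interval*. A corrected value for a
flagged beat depends on the next accepted beat, which is unknown mid-pass,
so the only non-circular single-pass reading of "previous accepted-or-
corrected interval" is to carry the last accepted value forward as the
reference; this also prevents one artifact from cascading flags down the
series. Flagged beats are then replaced by linear interpolation *over beat
index* (not time — the abscissa is being rebuilt) between nearest unflagged
neighbours; a flagged run touching either end takes the nearest unflagged
value. Exactly one pass is made: interpolated values are never re-examined,
so cleaning is idempotent on its own output whenever no interpolated value
re-triggers a rule. A series whose every beat is flagged is an error.

## Epoching

The retained span starts `discard_head` (default 300 s, poor signal quality
at hook-up) after time zero and is tiled by consecutive 300-s parent
windows; a trailing partial window is dropped. Each requested shorter scale
(30 s, 1, 2, 3 min) contributes one sub-epoch per parent with the same
midpoint, which makes the ultra-short vs 5-min pairing structural: agreement
statistics join on `(record_id, parent_index)`. A parent whose midpoint
falls in no labeled segment, or in an `excluded` segment, is dropped with
its sub-epochs (midpoint containment is the one unambiguous boundary rule
when segment edges cut through windows). Epochs with fewer than `min_beats`
(default 10) intervals are marked invalid and excluded downstream — sample
entropy and spectral estimates are meaningless on near-empty windows.

## Features

All standard deviations among the 22 features use the **population (1/n)**
normalization. With one convention everywhere, two exact identities follow:
`SD1 = SDSD/√2` and `RMSSD² = SDSD² + mean(Δ)²` (hence `RMSSD ≥ SDSD`);
with the sample (n−1) convention the second identity fails whenever the mean
successive difference is near zero, which is the typical case. `pNN50` and
`pNN20` divide by the number of RR intervals in the epoch, not the number of
successive pairs. `MeanHR`/`SDHR` summarize the instantaneous per-beat rate
`60000/RR_i` (bpm) — "SD of the heart rate" requires a per-beat HR series,
not `60000/MeanNN`. `NN50`/`NN20` are raw per-epoch counts and therefore
scale with epoch length; the surrogacy stage compares them across scales
regardless, deliberately.

### Spectrum

The Lomb–Scargle periodogram of the mean-subtracted tachogram is evaluated
against the true beat times — no resampling to an even grid. The frequency
grid is tied to the epoch length `T`: lowest frequency `max(1/T, 0.003)` Hz
(one full cycle must fit in the window), spacing `1/(4T)` (4× oversampling),
up to 0.4 Hz. Short epochs therefore stay computable, with VLF/LF
necessarily unreliable below the window's resolution — a 30-s window cannot
see 0.04 Hz. The raw periodogram is rescaled so its trapezoidal integral
over the grid equals the series variance (ms²), making `TP ≈ SDNN²` and
giving band powers physical units. Band powers assign each trapezoid
segment to the band containing its midpoint — VLF `(f_min, 0.04]`, LF
`(0.04, 0.15]`, HF `(0.15, 0.4]` Hz — so `TP = VLF + LF + HF` holds exactly
by construction, and `LFnu + HFnu = 1` whenever LF+HF > 0. A zero-variance
epoch yields an all-zero PSD, not an error; `LF/HF` with zero HF propagates
as NaN, never infinity.

### Non-linear

Poincaré descriptors come from the lagged pairs `(RR_i, RR_{i+1})`:
`SD1 = SD((RR_{i+1}−RR_i)/√2)`, `SD2 = SD((RR_{i+1}+RR_i)/√2)`, with the
Toichi indices `CSI = SD2/SD1` and `CVI = log10(16·SD1·SD2)`. Sample
entropy uses the field-standard defaults `m = 2`, `r = 0.2·SDNN` of the
epoch (fallback 1 ms when SDNN = 0), Chebyshev distance, self-matches
excluded, and the counting convention in which both the m- and
(m+1)-template counts run over the `n−m` templates that admit an extension.
`A = 0` or `B = 0` yields NaN. Undefined values propagate as NaN throughout
the feature table; downstream statistics drop them pair- or row-wise and
report the n they actually used, never absorbing them as zeros.

## Statistics

The stress contrast is a two-sided pooled-variance Student's t-test per
feature and scale, epochs pooled across records as independent observations
(no per-driver random effect; a Welch variant sits behind a flag). Trend
marks: direction of `mean(high) − mean(low)`, with a `_sig` suffix when
p < α (default 0.05); an exactly zero difference is marked `down` with a
`tie` annotation so output is deterministic. No multiple-testing correction
is applied to the per-feature p-values; a Holm-adjusted column is emitted
alongside as supplementary output, leaving the replicated procedure
untouched.

Agreement between an ultra-short scale and the 5-min reference is assessed
within each stress level separately: Spearman rank correlation
(average-rank ties, t-approximation p-value) and Bland–Altman bias with
95% limits of agreement `bias ± 1.96·SD(d)` (sample SD — the standard in
method comparison), where `d = ultra − 5min` on parent-matched pairs. A
missing value drops the pair, never the feature; fewer than 5 pairs is an
error naming the cell.

Surrogate selection at scale *s* requires (a) a significant trend at *s*
with the same direction as the (also significant) 5-min trend, and (b)
ρ > 0.7 with p < 0.05 at *s* in **both** stress levels. Requiring both
levels is the strict reading of "significant correlations … between the
low-stress and high-stress levels" and is the interpretation under which
the published feature sets are self-consistent. Decisions carry a
pass/fail reason per criterion. The all-scale surrogate set is the features
selected at every ultra-short scale.

## Classification harness

Ten independent stratified 70/30 splits, seeds derived deterministically
from one master seed (`numpy.random.SeedSequence`); a split missing a class
is redrawn with the next derived seed and logged. Within each training
split, a 10-fold stratified cross-validated grid search by accuracy selects
hyperparameters; features are z-scored inside each CV training fold and the
final scaler is fit on the full training split only (KNN and RBF-SVM are
scale-sensitive). Grids: SVM C ∈ {0.1, 1, 10, 100} × γ ∈ {scale heuristic,
0.01, 0.1, 1}; KNN K = 1..10 (Euclidean); forests and AdaBoost stumps
(depth-1 trees, learning rate 0.1) with 50/100/150 trees. Everything else
is pinned at the library defaults explicitly in `default_specs()` so
defaults cannot drift. Sensitivity and F1 treat **high stress as the
positive class** (detecting stress is the clinically relevant positive).
Reports store the per-split confusion matrices, so every aggregate is
recomputable from raw counts, and a fixed seed reproduces reports
bit-identically. Random epoch-level splits mean epochs of one recording can
appear in both train and test; per-subject splitting is deliberately out of
scope.

## Synthetic studies

The generator is a transparent statistical emulator, not a physiological
model: beat-by-beat synthesis

```
rr_i = mean_rr + lf_amp·sin(2π f_LF t_i + φ) + hf_amp·sin(2π f_HF t_i + ψ) + e_i,
e_i = knob·e_{i−1} + N(0, noise_sd),   t_i accumulated from the rr themselves
```

with oscillator frequencies drawn once per record from narrow bands around
0.1 and 0.25 Hz (fixed frequencies would align with analysis grids and mask
leakage behaviour). State parameters blend linearly over 30 s after each
segment transition — heart rate shifts over tens of seconds, and an
instantaneous mean-RR step would itself trip the 20% ectopic rule.
Artifacts are injected post hoc with per-beat probabilities: outliers as
draws outside 280–1500 ms, ectopics as multiplicative factors outside
[0.8, 1.25] (guaranteeing a 20%-rule violation against an undisturbed
neighbour), with all injected positions recorded as ground truth.

The default study is one long record standing in for a pooled multi-subject
corpus: low/high/low blocks of 6000/6300/5700 s giving 59 parent epochs
(38 low, 21 high). Default states: low stress (mean 850 ms, LF amp 12 ms,
HF amp 10 ms, innovation SD 28 ms, AR coefficient 0.35) is
jitter-dominated; high stress (mean 700 ms, LF amp 60 ms, HF amp 5 ms,
innovation SD 4 ms, AR coefficient 0.20) is strongly LF-dominated and
nearly deterministic. These defaults encode the canonical stress contrasts
— shorter intervals, faster heart rate, higher overall variability, a much
larger LF/HF ratio, lower sample entropy — with effect sizes large enough
that the trends are detectable even on 30-s windows, where the sample-
entropy estimator (≈40 beats, ≈38 templates) saturates near the log of the
countable template pairs and has a standard deviation of ~0.4 across
epochs. The sizing rationale: the t-test power at 30 s for SampEn is the
binding constraint of the whole design, and with these defaults the
designed trends are recovered at all five scales in 20/20 design
replicates.

What the generator does **not** emulate, hence what passing tests do not
show about real data: absolute HF power and NN50 *fall* under the default
high-stress state (its variance is concentrated in the LF oscillation),
whereas field recordings typically show them rising with stress alongside
overall variability; there is no respiratory coupling, no circadian or
slow drift, and no between-epoch heterogeneity within a state. The last
point matters for the agreement analysis: with a stationary state, a 30-s
window shares only ~10% of its beats with its parent and its MeanNN is
essentially independent noise around the same constant, so cross-scale
Spearman coefficients at 30 s are near zero on synthetic data — unlike real
recordings, where slow between-epoch drift makes 30-s MeanNN track the
5-min value tightly. The surrogate-selection machinery is therefore tested
on constructed scale-stable feature tables (where ground truth is exact)
rather than on the generator's output, and the full pipeline falls back to
the canonical quartet {MeanNN, SDNN, NN20, MeanHR} when the synthetic study
yields no all-scale surrogate.

## Numerical and degenerate-input choices

* All seeds below 2³¹; every stochastic component (generator, splits,
  folds, forest/boosting randomness) derives from one master seed.
* Tables are written as CSV with 12 significant digits; a write→read→write
  round trip is byte-identical.
* Epoch arithmetic is exact in integer seconds; sub-epoch midpoints equal
  parent midpoints exactly, not approximately.
* A cleaning pass that flags every beat, a design matrix with one class,
  an agreement cell with < 5 pairs, and a t-test group with < 2 values are
  errors naming the offending object; an epoching that yields no epochs is
  an empty result, not an error.

## Problem sizes

The test suite and the acceptance script run on synthetic studies of
~23 000 beats (5 h of simulated recording, 59 parent epochs, 295 feature
rows) and use 10–20 replicates for stochastic checks; these sizes give the
statistical headroom described above while keeping a full run in minutes on
one CPU.
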