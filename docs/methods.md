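# Methods

`ehgkit` implements a complete electrohysterogram (EHG) analysis pipeline
for term/preterm discrimination: signal characterization, class balancing,
wrapper feature selection by a genetic algorithm (GA), and evaluation of
simple classifiers and their majority-vote ensemble under a repeated
stratified holdout protocol. This note documents the model and the design
decisions, their defaults, and what the synthetic experiments do and do not
establish.

## Signal model and preprocessing

Input recordings are three bipolar abdominal channels (S1, S2, S3) sampled
at 20 Hz, with a term/preterm label and five obstetric covariates (maternal
age, parity, abortions, weight, gestational week at recording — "wog").
Only expert-marked physiological segments are analyzed; artifact detection
is out of scope and segments are accepted as input intervals.

Each usable segment is band-pass filtered into four canonical bandwidths —
0.1–4 Hz (whole EHG), 0.34–4 Hz (Fast Wave High, excitability-related),
0.2–0.34 Hz (Fast Wave Low, propagation-related) and 0.34–1 Hz (FWH below
1 Hz, where the signal-to-interference ratio is better). The filter is a
4th-order Butterworth applied forward–backward (zero phase). The literature
convention for EHG is zero-phase IIR filtering; the order is a conventional
compromise between roll-off and ringing in the very narrow 0.2–0.34 Hz
band. Filtering precedes windowing (each segment is filtered whole, then
cut), so windows carry no per-window filter transients. Analysis windows
are 120 s with 50 % overlap (2400 samples; starts advance by 60 s);
windows that would cross a non-usable gap are dropped, not shortened.

## Feature inventory (203 features)

Per channel, 66 descriptors:

* **Temporal (4):** peak-to-peak amplitude (App) in each of the four bands.
* **Spectral (18), computed from the Welch spectrum of the whole-band
  (0.1–4 Hz) window:** Teager energy (on the whole-band time series), mean
  frequency in 0.1–1 Hz, dominant frequency in 0.2–1 Hz and 0.34–1 Hz,
  power-spectrum deciles D1–D9 in 0.34–1 Hz (D5 is the median frequency),
  normalized energies of 0.2–0.34 / 0.34–0.6 / 0.6–1 Hz relative to the
  total 0.1–4 Hz power, the high/low energy ratio
  P(0.34–1)/P(0.2–0.34), and the spectral moment ratio M(−1)/M(5) with
  M(k) = Σ f^k P(f) over 0.1–1 Hz (a Dimitrov-style index that falls as
  energy shifts to higher frequency).
* **Non-linear (11 × 4 bands = 44):** sample entropy, fuzzy entropy,
  spectral entropy, Lempel-Ziv complexity (binary and 6-state), time
  reversibility, Katz fractal dimension, and the Poincaré descriptors SD1,
  SD2, SDRR and SD1/SD2 — each computed on each band-filtered window.

Three channels times 66 plus the five obstetric covariates gives 203
features. Per-window values are collapsed to the per-recording **median**,
one robust representative value per feature. The band assignments of the
spectral set (mean-frequency band 0.1–1 Hz, decile band 0.34–1 Hz, the
normalized-energy denominator) are fixed by this package as the only
arrangement consistent with the 66-per-channel inventory; all are
config-exposed.

The Welch estimator uses 1024-sample Hamming segments with 50 % overlap,
one-sided, density scaling (Parseval holds to ~1 % for broadband input).
Band integrals use half-open frequency intervals [f_lo, f_hi) so adjacent
sub-bands never double-count a bin.

### Non-linear kernel conventions

The entropy parameters are the EHG-literature defaults: embedding m = 2,
tolerance r = 0.15 × window SD (per band), fuzzy exponent 2. Sample
entropy is −ln(A/B) with Chebyshev template matching (d ≤ r) and
self-matches excluded; if no m+1 pair matches, the theoretical ceiling
ln(N−m) + ln(N−m−1) − ln 2 is returned as a documented sentinel; a window
with B = 0 or zero variance raises and is skipped. Fuzzy entropy uses
mean-centred templates and membership exp(−d²/r); memberships whose
exponent exceeds 45 are skipped (they are < 3 × 10⁻²⁰ and cannot move a
double-precision sum) — this is a pure speed device, verified against the
exhaustive computation. Lempel-Ziv uses the exhaustive (LZ76) parse; the
binary symbolization thresholds at the median and the 6-state variant uses
equiprobable quantile bins (ties to the lower bin); the count c is
normalized as C = c·log_α(N)/N with α the alphabet size so the binary and
6-state indices share a scale. Time reversibility is the un-normalized
third moment of lag-1 differences. Katz's fractal dimension uses one
abscissa unit per sample; a constant window is degenerate (raises) since
its waveform has no extent. Degenerate windows are skipped per feature and
the recording's median is taken over the remaining windows; a subject
missing any aggregated feature is dropped with a warning.

## Screening, balancing, partitions

A two-sided Wilcoxon rank-sum test (exact for small untied samples,
asymptotic otherwise) compares term vs preterm per feature, on the
original unbalanced table only — synthetic rows are rejected by an explicit
leakage guard. The screen is descriptive: it never removes features before
the GA, because individually non-significant features can carry
complementary information. No multiple-testing correction by default
(a Benjamini–Hochberg option exists).

SMOTE (k = 5) oversamples the minority class to parity: each synthetic row
is x + u·(x_nn − x) with u ~ U(0,1) and x_nn one of the k nearest minority
neighbours. Distances are Euclidean on z-scored features (the features mix
Hz, mV and mV³ scales); interpolation is in the original space, so every
synthetic value lies between its parents'. Balancing the whole table
before partitioning reproduces the reference protocol faithfully but leaks
synthetic-parent information across splits; this caveat is logged, and
fold-wise balancing is available by balancing sub-tables instead.

The holdout scheme draws stratified random train/validation/test thirds of
the balanced table (default 30 partitions; class proportions equal to
within one row).

## GA wrapper selection

Chromosomes are binary masks over the features. Fitness is
mean validation F1 (preterm positive, over all partitions) × (NFeat −
NCFeat); F1 is kept as a fraction so the reduction term dominates ties —
equal-performing smaller subsets always win, and selecting all features
scores exactly zero. Defaults mirror the reference setup: population =
genome length (203), tournament size 2, elite count 2, arithmetic
crossover with probability 0.8, uniform mutation at 0.01, termination when
the best fitness improves by < 10⁻⁶ over 150 consecutive generations
(capped at 1000).

Design decisions where the source protocol is underdetermined:

* **Arithmetic crossover on binary genes** draws one convex weight u per
  child and rounds u·p1 + (1−u)·p2, which returns the nearer parent's
  value on every gene (exact halves are fair-coined). Exploration then
  rests on the Bernoulli(0.5) initial population and the mutation
  children; this preserves the operator's averaging semantics while
  keeping genes binary.
* **Offspring composition:** of the non-elite children, 80 % come from
  crossover of tournament parents and 20 % are mutation-only tournament
  parents.
* **All-zero masks** are assigned minimal fitness (−inf) without fitting.
* Fitness values are cached by mask, and the GA is deterministic under its
  seed. Termination watches the best fitness only.

Test rows are never touched during fitness evaluation; each classifier's
own optimized mask is used for its final train/validation/test evaluation.

## Classifiers, ensemble, comparison

KNN (k = 5, odd to avoid internal vote ties), LDA (SVD solver; a singular
covariance falls back to a shrinkage solver with a warning) and logistic
regression (maximum likelihood with a negligible ridge for stability).
Features are z-scored with statistics fit on the training third only.
Scores are preterm posteriors (LDA/LR) or the preterm neighbour fraction
(KNN); labels threshold at 0.5. The ensemble takes the per-row majority
label; its ROC score is the mean of the base scores (label-level voting
alone defines no ROC). Metrics: accuracy, F1, sensitivity, specificity,
PPV, NPV (confusion-matrix definitions, preterm positive, zero-division →
0) and trapezoidal AUC. Classifiers are compared by a Friedman test on
partition-wise F1 ranks with Nemenyi post-hoc pairwise decisions at
α = 0.05 (critical difference from the studentized range at large df);
pairwise claims are suppressed when the omnibus test is not significant.
Between-partition variability is summarized as the coefficient of
variation per metric and classifier, with min/mean/max across the base
classifiers.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without
clinical data. Per subject: three channels of pink background noise
(power slope −1, independent per channel, default 0.05 mV), plus
band-limited noise bursts (center ± 0.08 Hz, Hanning envelope, duration
U(30, 90) s) arriving as a Poisson process (default 0.3/min), shared
across channels with per-channel gain ~ N(1, 0.15). Class effects are
planted through the burst parameters: term bursts default to 0.36 Hz /
0.20 mV and preterm to 0.44 Hz / 0.28 mV, reproducing the directions
reported for approaching labor (higher frequency content, larger
amplitude). Obstetric covariates are truncated Gaussians with the
published demographic means/SDs of the two groups, and wog scales burst
amplitude by 1 + 0.03·(wog − 27) so the covariate carries real signal.
Recordings default to the full record usable; an option punches artifact
gaps to exercise segment exclusion.

What the generator does **not** emulate: Alvarez/Braxton-Hicks waveform
morphology, tocographic context, electrode placement effects, non-
stationarity across gestation, or any physiologically calibrated effect
size — the planted effects are tuning knobs, not estimates. Passing
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and sensitive in the planted directions, not that any particular
clinical performance level would be attained on real cohorts.

## Scaled study sizes

Full-scale runs (326 subjects × 30 min × GA with population 203) are
supported by the code but the packaged experiments run at desk scale,
chosen once as the package's own study conditions: a 60 term / 12 preterm
cohort of 240-s recordings (3 windows per channel), 10 partitions, GA
population 40 with a 25-generation stall window capped at 60 generations —
enough for the reduction term to prune the mask to a compact subset, which
matters because base classifiers fit on 40-row training thirds are
unstable when the mask keeps hundreds of features; the zero-effect null
study uses
20 + 20 subjects and 30 partitions; the planted-recovery experiment uses
a 20-feature table (5 informative, 150 rows), population 30, 40
generations, mutation 0.05 (a higher rate than the 203-gene default —
on a 20-gene genome the 0.01 rate would flip ~0.1 genes per child,
starving the search of variation). The planted problem hides the class
signal along the informative block's common direction with a strong
orthogonal confound, so discriminability rises steeply and monotonically
with the number of informative features included — a landscape where
recovering the subset is both non-trivial and achievable.

## Known limitations

* The absolute performance figures of any real-cohort study are not
  reproducible from synthetic data; only structural and directional
  properties are asserted.
* Whole-table SMOTE (the faithful default) optimistically biases
  validation/test estimates; use fold-wise balancing for honest
  generalization figures.
* The spectral-set band assignments are a documented reconstruction (the
  66-per-channel inventory admits exactly one arrangement, but band
  choices for mean frequency and deciles follow the FWH-emphasizing
  convention of prior EHG work).
* LDA on more features than training rows relies on the SVD solver's
  pseudo-inverse behaviour; results are well-defined but shrinkage may be
  preferable for heavily masked tables.
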