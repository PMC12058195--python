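# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the parameters that matter, in the order the pipeline runs.

## Behavioral target

Continuous slider logs (1–25 integer scale, 13 = neutral) are step
functions: the slider holds its value between key presses. Resampling takes
the value prevailing at the **end** of each TR interval `[k·tr, (k+1)·tr)`
(last value carried forward). The convention — interval end rather than
start or midpoint — is a choice; it is configurable at the resampling
helper and matters only when a press lands inside the interval.

Per rater, segment series are concatenated, optionally cropped by a TR
exclusion list (non-movie filler), and z-scored across the full length
(sample sd, denominator n−1, everywhere in the package). A rater who never
moves the slider carries no signal; their z row is zeroed with a warning.
The group target is the elementwise mean of the z-scored panel.

**ISC.** Each rater's Pearson correlation with the leave-one-out group mean
is Fisher-z transformed; the summary is `tanh(mean(atanh(r)))`, with r = ±1
clipped to ±(1−1e−15) before `atanh`. Significance: each rater's z value is
given a random sign with probability ½, the signed values are averaged, and
the one-tailed (greater) permutation p is `(1 + #{null ≥ observed})/(1+N)`
with floor `1/(N+1)`. *Known limitation:* the leave-one-out correlations
share the group mean and are positively dependent; independent sign flips
ignore that dependence, so the test is liberal (on independent white-noise
panels the empirical type-I rate is roughly 2–4× nominal). This is a
property of the procedure itself, kept as specified; the test suite asserts
the summary's unbiasedness and only a loose bound on the rejection rate.

**Hemodynamic model.** The group target is causally convolved with the
canonical double-gamma HRF — response gamma shape 6, undershoot shape 16,
unit scale (seconds), undershoot ratio 1/6, kernel length 32 s — sampled at
the TR and truncated to the input length. Transform order is z-score →
HRF-convolve → taper-smooth; the order is a documented choice (the
alternatives differ only through the smoothing's interaction with the
z-scoring constant).

**Taper smoothing.** The value at TR t is the Gaussian-weighted mean (sd
σ = 3 TR by default) over a window of `window_tr` TRs centered at t
(for even lengths the extra sample sits on the left), truncated at the
series boundaries and renormalized to sum 1. The same weights define the
dynamic-connectivity windows, so the behavioral target and the FC series
share one timescale and one length.

**Positivity/negativity.** On the *raw* (un-normalized) group mean, TRs
strictly above the neutral value are "positive" moments and TRs strictly
below are "negative"; exact-neutral TRs belong to neither. Retained TRs are
concatenated in order and re-processed (z-score, HRF, taper).

## Dynamic functional connectivity

Edges are indexed row-major over the upper triangle (i < j); 122 ROIs give
7381 edges. For each TR, each edge's value is the **fully weighted** Pearson
correlation (weighted means and variances under the taper weights) of the
two ROI series in the centered window, clipped to ±(1−1e−7) and Fisher-z
transformed. Weighting rather than mask-then-correlate is a choice implied
by the Gaussian taper; the two differ at the third decimal for typical
windows. Zero-variance windows yield z = 0 with a logged count rather than
NaN, so downstream selection stays total. One output column per input TR;
windows at step 1 TR.

Confound regression is ordinary least squares with an intercept: low-level
stimulus features (10 series) are removed from each ROI's BOLD series;
framewise displacement is taper-smoothed with the same window spec and
removed from each edge's FC series. Collinear design columns are dropped
with a warning; constant FD degenerates to demeaning.

## Connectome-based predictive modeling

**Selection.** Per training subject and edge, the Pearson correlation
between the edge's Fisher-z FC series and the target; these correlations are
Fisher-z transformed (variance stabilization; a toggle reverts to raw r) and
tested against zero across subjects with a two-tailed one-sample t-test.
Edges with p < α (default .01) are selected; the sign is the sign of the
mean transformed correlation. Selection correlations are computed on the
stored Fisher-z FC values.

**Regression.** Support-vector regression with a radial-basis kernel and
library-default hyperparameters (C = 1, ε = 0.1, γ = 'scale'), recorded on
the fit. Features are standardized with training-set statistics only and the
frozen statistics are applied to test data. The group target is tiled once
per training subject (only group-level ratings exist; subject-specific
targets are out of reach by design).

**Cross-validation.** Leave-one-subject-out; the held-out subject enters
neither selection nor training (verified by a leakage test that corrupts the
held-out subject's data and asserts the fold's artifacts are unchanged).
Fold accuracy is the Pearson correlation between the predicted and group
target series, summarized as `tanh(mean(atanh(r)))`; RMSE is computed after
standardizing the prediction against its own mean/sd (raw-scale toggle
available), which puts chance-level performance near √2·sd and perfect
anticorrelation near 2. The **consensus mask** is the intersection of all
fold masks restricted to sign-consistent edges (conflicting edges dropped
with a warning); it is the dataset's arousal network and the feature set for
across-dataset prediction, where a single model is fit on all training
subjects (one or several datasets) and scored per test subject. Edge-index
hashes guard against mixing parcellations.

**Training-sample thinning (`train_stride`).** Windows at step 1 TR overlap
by all but one sample, so adjacent training rows are nearly duplicates. The
`train_stride` option keeps every k-th TR of the *training* rows only —
predictions and scores always use the full grid — and exists to bound the
quadratic cost of kernel SVR on concatenated multi-subject series. The
package's own end-to-end checks run the 16-subject × 500-TR condition at
stride 5 (1500 training rows per fold) and the smaller conditions at stride
2–3, with the empirical statistic and its permutation null computed at the
same stride so the comparison is internally consistent. At these strides
the thinning changes fold accuracies at the second decimal.

## Surrogate and resampling statistics

**Phase randomization** keeps the discrete-Fourier amplitude spectrum
exactly (random uniform phases on the free bins; DC and Nyquist untouched),
hence preserves mean, variance (Parseval) and autocorrelation while
destroying alignment with the stimulus. Null distributions for prediction
accuracy re-run the pipeline per surrogate:

- *Within-dataset*: selection, training and testing all use the same
  surrogate target. The model may learn arbitrary stimulus-locked features
  that correlate with the surrogate, so this null is conservative and its
  mean sits well above zero — the expected behavior, reproduced on
  synthetic data.
- *Across-dataset*: the feature mask is held fixed (recomputing the
  consensus mask per iteration would require a full cross-validation per
  surrogate; the published procedure is ambiguous and this reading matches
  "surrogate on the training target, tested against the true test
  target"); the regressor is re-fit on the surrogate training target and
  evaluated against the true test target. Nothing learned from the
  surrogate transfers, so this null centers on zero. A toggle also
  randomizes the test-side target.

The permutation p-value is `(1 + #{null ≥ emp})/(1 + N)` (≥ rather than >:
the conservative convention), mirrored for "less" tails (used for RMSE).
Circular-shift nulls exclude the zero shift and enumerate all distinct
shifts when N allows. The TOST equivalence test runs both one-sided t-tests
on Fisher-z fold accuracies against `atanh(±0.1)` bounds by default and
reports the larger p. BH-FDR is the standard step-up (statsmodels).

## Network anatomy

The hypergeometric overlap test implements the survival formulation
`P(X > x) = 1 − hygecdf(x, M, K, n)` literally, with an `inclusive` flag
for `P(X ≥ x)` — the two differ negligibly at M = 7381 but matter on toy
instances, and both are exposed because the off-by-one is a classic
pitfall. The Jaccard test re-draws **both** sets' positions uniformly with
sizes fixed (a symmetric-null choice; a single-set shuffle differs only by
exchangeability bookkeeping). Enrichment covers all 36 cells (8 within-
network + 28 between-network) per sign, with a uniform re-placement null
and BH-FDR per sign family (the alternative — one family across both signs
— is a trivial variant). Note that an N-permutation null floors p at
1/(N+1); with 36 cells the rank-1 BH threshold is q/36, so at least
~36/q − 1 permutations (719 at q = .05) are needed before any cell can be
declared significant — the default is 10000.

The bundled 122-ROI → 8-network table (`data/roi122_networks_synthetic.tsv`)
is a synthetic stand-in with plausible cortical block sizes and the final 8
ROIs subcortical; real analyses should substitute an atlas table.

## Synthetic data generator

The generator defines the package's study conditions. Defaults mirror a
movie-watching dataset: 16 subjects, 60 ROIs (desk-scale stand-in for 122),
500 TRs at 1.5 s, 30 raters on the 1–25 scale, latent smoothness 10 TR,
coupling 0.6 (the empirical arousal–FC coupling strength is not
characterized anywhere; 0.6 is a test-convenience default, and the
recovery checks run at 0.8 to leave headroom for estimation noise).

- **Latent arousal state**: Gaussian white noise convolved with a Gaussian
  kernel (sd = `smoothness_tr`), standardized. Simple, with controllable
  autocorrelation; requires series at least 10 kernel-sd long.
- **Coupling**: each planted edge's target correlation is
  `ρ(t) = 0.9·coupling·sigmoid(latent(t))` (the 0.9 ceiling keeps Fisher-z
  values bounded). Both ROIs of a planted edge receive a shared Gaussian
  component with amplitude `a(t) = sqrt(ρ/(1−ρ))·noise_sd`, which makes the
  instantaneous model correlation exactly ρ(t) — so ground truth is
  available for recovery tests. Exactness requires ROI-disjoint planted
  edges; the default edge picker guarantees that.
- **Raters**: right-continuous step functions; presses arrive as a Poisson
  process (`rater_press_rate` per minute); at each press the slider moves
  to the min-max-rescaled latent plus AR(1) noise (persistence 0.8, sd
  `rater_noise_sd`), rounded half-away-from-zero to the integer grid and
  clipped to [1, 25].
- **Nuisance**: six continuous smoothed-noise features (hue, saturation,
  intensity, motion energy, amplitude, pitch) and four persistent 0/1
  Markov indicators (face, indoor, text, music); framewise displacement is
  gamma-distributed with occasional exponential spikes. A leakage mode
  injects the latent into the first feature so confound regression
  measurably removes planted signal.
- **Dataset pairs** share a controlled fraction of planted edges
  (`round(f·n)` common, the rest disjoint) to probe cross-dataset
  generalization.
- **Seeding**: one master seed; every component draws from a sub-stream
  keyed by (seed, component, index), so adding subjects or raters never
  perturbs existing ones and fixed seeds give byte-identical datasets.

**What the generator does not emulate:** hemodynamic lag in the BOLD series
(the latent modulates correlations instantaneously, while the behavioral
target is HRF-convolved — the smooth latent makes the resulting few-TR
misalignment a mild attenuation, not a confound), scanner noise spectra,
spatial autocorrelation among ROIs, physiological confounds beyond FD, and
rater reaction-time lag. Passing tests therefore demonstrate that the
pipeline recovers the planted statistical structure under idealized noise,
not that real fMRI effect sizes match.

## Problem sizes used by the end-to-end checks

Chosen as the package's own desk-scale study conditions: the main recovery
check runs 16 subjects × 60 ROIs × 500 TRs at coupling 0.8 with a
100-iteration within-dataset null (stride 5); the no-signal control runs 20
seeds at 8 × 30 × 240 with 19-iteration nulls; cross-dataset checks run 20
seeds of paired 8 × 48 × 300 datasets (12 planted edges, shared fraction 1
vs 0, stride 3); selection calibration runs 20 seeds of 16 × 30 × 300 pure
noise. The synthetic ISC and enrichment checks use smaller instances sized
for exact or near-exact oracles.

## Known limitations

- The sign-flip ISC test is liberal under the null (see above).
- Kernel SVR cost grows quadratically with training rows; very long
  multi-dataset concatenations should raise `train_stride` or expect long
  fits.
- The consensus mask's sign-consistency rule can drop genuinely selected
  edges whose sign flips between folds at weak coupling; these are logged.
- Enrichment p-values are permutation-based; with the default 10000
  iterations the floor is ~1e−4, which is fine for 36-cell FDR but not for
  genome-scale families.
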