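# Methods

This note documents the models, the statistical procedures, the synthetic
data they are validated on, and the numerical and design choices a
maintainer would want to know. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Input is a labeled trial tensor (trials × channels × samples), two classes
(left/right-hand motor imagery), with a montage giving schematic 2-D
electrode positions. The canonical trial is 7 s at 250 Hz (1751 samples,
endpoint-inclusive): fixation from 0 s, cue at 2 s, imagery until ~6 s.
Named intervals segment it — dT0 = [0.5, 1.5] s (reference), dT1 = [0, 2]
(task-negative), dT2 = [0.8, 2] (cue onset), dT3 = [2.6, 4.6] (motor
imagery), dT4 = [3.8, 5.8] (decay), dT5 = [4.4, 6.4] (break).

**Filter bank.** 4–40 Hz tiled by bands of width 4 Hz stepped by 2 Hz
(consecutive bands share 2 Hz), giving `floor((40−4−4)/2)+1 = 17` bands.
The width is a package choice: it is the only integral-Hz tiling that yields
17 bands with a 2 Hz overlap over 4–40 Hz, and it covers mu and the three
beta sub-bands ([16–20], [20–24], [24–28] Hz) cleanly. Band-passing is a
zero-phase forward-backward Butterworth of order 4 per pass; the two-pass
magnitude response is |H|², so power calculations against the filter use
|H|⁴.

**Surface Laplacian.** Small Laplacian: each channel minus the mean of its
montage neighbors (neighbors = electrodes within 1.1 grid units, i.e. the
orthogonal nearest neighbors). Channels without neighbors pass through with
a log record. The operator is linear and common-mode rejecting. For the
connectivity stage the data are additionally re-referenced to Cz, and Cz is
excluded from the pair set (keeping a zero reference channel in the pair
statistics would only add structural zeros).

**Window grids.** Fixed-step grids start at 0 with step τ(1−overlap); the
last window lies fully inside the trial, so τ = 1 s with 90% overlap over
7 s gives `floor(6/0.1)+1 = 61` positions. The per-sample grid places one
position at every sample instant, endpoints inclusive: 1751 positions for
the canonical trial. Windows are half-open [start, start+τ) in samples.
Defaults per extractor: τ_J = 1 s with 90% overlap (CSP), τ_φ = 0.1 s
non-overlapping (wPLI), per-sample (ERD/S).

## Feature extractors

**CSP.** Class covariances are the plain average of per-trial X Xᵀ over the
window samples (no trace normalization), optionally shrunk toward the scaled
identity by γ ∈ [0, 1]; γ = "auto" uses the Ledoit-Wolf coefficient
estimated from the pooled window samples. `csp_fit` solves
Σ_l w = J (Σ_l + Σ_l′) w and keeps the k largest- and k smallest-J
eigenvectors (k = 3 by default, so 2k = 6 components; with 17 bands a
window slice carries 102 feature columns). Eigenvalue identities: equal
class covariances give J ≡ 0.5; swapping labels maps J to 1−J. Rows of W
are ℓ₂-normalized with the largest-magnitude entry positive (the quotient
is sign- and scale-invariant; the convention makes outputs reproducible),
and the pattern matrix W⁻ (columns of the inverse of the full eigenvector
matrix) is rescaled so W·W⁻ stays the identity on the retained subspace.
θ_J is the absolute first pattern column (the highest-J component only),
max-normalized to [0, 1] per (f, τ) cell; the normalization formula is a
package choice since only the codomain is prescribed.

**Accuracy time-courses.** Per window position, the feature block pools all
bands (n_bands × 2k log-variance features). The classifier is a shrinkage
LDA under seeded stratified 10-fold cross-validation — the de-facto standard
for CSP log-variance features; nothing in the pipeline fixes it, so it is
configurable. CSP filters are refit on every training fold: fitting them
once on all trials leaks the test fold into the filters and inflates
accuracy far above chance even on label-free noise (observed directly in
development on permuted labels). A small fixed identity shrinkage
(γ = 0.01) guards the fold covariances. Per-trial covariances are
precomputed per (band, window) so a fold's class covariance is a mean of
slices and a trial's features are `log diag(W C_n Wᵀ)`; zero variances are
floored at 1e−20 before the log.

**wPLI.** Coefficients come from complex Morlet wavelets (7 cycles at the
band center; configurable, ≥ 3). The estimator is the standard weighted
phase lag index on the per-trial cross-spectrum S_n, with Im S_n averaged
over the window samples before the trial expectation; it returns 0 when the
denominator vanishes, with the vanishing test taken relative to the
cross-spectrum magnitude (a constant zero/π lag leaves only rounding noise
in Im S). Properties: constant non-trivial lag → 1; zero-lag (volume
conduction) → 0 in expectation; the finite-trial null is
|Σ x_n|/Σ|x_n| ≈ √(π/2n)·|Z| for symmetric weights, i.e. ~0.09 at
n = 200 trials — baseline levels in wPLI maps are a noise floor, not
coupling. Baseline normalization divides each (pair, band) time-course by
its dT0 mean (subtraction available); division amplifies noise on null
pairs whose baseline is near the floor, so recovery analyses on raw φ are
also exposed. Node strength sums φ over the pairs containing each channel;
θ_φ is the max-normalized node strength per cell.

**ERD/S.** ξ(τ) is the trial mean of squared band-passed samples on the
per-sample grid (smoothing is an explicit optional moving average, default
off, so the definition stays exact); ζ = ξ/ξ̄ − 1 with ξ̄ the dT0 mean.
Channels with identically zero reference power are flagged NaN (undefined,
not zero). Significance: ζ differs from 0 exactly when the trial-mean power
difference d(τ) = ξ(τ) − ξ̄ does, and d is an iid mean over trials, so the
mask uses a seeded studentized (bootstrap-t) interval on d (1000 resamples).
A plain percentile bootstrap was measured at 2–4× the nominal α = 0.01
type-I rate on null cohorts (the usual skew miscalibration for
chi-square-like power values); the studentized interval restores ~nominal
calibration, which the acceptance suite verifies (≥ 1000 null cells).

## Group stage

**Channel relevance.** Per (subject, band, interval, channel), a two-sided
Mann-Whitney test compares the two classes' θ values across the interval's
window positions; for the label-merged CSP dynamics, the interval is
contrasted against the task-negative dT1 instead (the quotient merges
labels, so a temporal contrast is the only available comparison). Window
positions are subsampled with a decorrelation stride (default 0.25 s,
matching the ~4 Hz analysis bandwidth): consecutive positions of
overlapping or per-sample grids are strongly autocorrelated and would
invalidate the rank test's independence assumption. A 2 s interval then
yields 9 samples (≥ 8 required). Kolmogorov-Smirnov normality and Bartlett
homoscedasticity diagnostics are recorded per cell but never alter the test.

One inherent property worth knowing: for ζ-based dynamics each class is
referenced to its *own* baseline estimate, so under the null the two series
differ by a shared random offset (baseline estimation error). This inflates
the raw per-cell Mann-Whitney rate (~3× at α = 0.05 under the default
cohort sizes) independently of trial count; it is a property of
class-specific baseline referencing, not of the implementation. The
FDR-corrected discovery proportion on null cohorts remains controlled
(measured in the acceptance suite), which is the quantity the group stage
consumes.

**pFDR.** Storey's positive-FDR: π̂₀(λ) = #{p > λ}/(m(1−λ)) on
λ ∈ {0.05, …, 0.95}, extrapolated to λ → 1 by a cubic fit; q-values by the
usual step-up accumulation with the π̂₀ factor. Families with fewer than 30
p-values fall back to π̂₀ = 1 (the smoother is unstable there), and fewer
than 10 fall back to Benjamini-Hochberg outright; BH is also available
explicitly. pFDR discoveries are a superset of BH's whenever π̂₀ ≤ 1 (a
property test). The correction family pools all (subject × channel)
p-values of one (band, interval) cell; the family definition is
configurable since nothing pins it down further.

**Aggregation.** Group dynamics are masked means: per cell, the mean of θ
over subjects whose corrected κ = 1 there, with the contributing count
recorded as support. Zero-support cells are NaN (undefined, never zero);
cells below ceil(0.5·M) support are marked unreliable. The combination rule
is the package's choice; the masked mean realizes "common = present in many
subjects" literally and keeps provenance auditable.

**Literacy split.** The predictor is the per-subject (mean, sd) of the
accuracy time-course. The ceil(0.10·M) points with the largest Mahalanobis
distance to the sample center are trimmed (singular predictor covariance
falls back to standardized Euclidean; distance ties break toward the higher
subject index); the assignment cut is the mean accuracy of the retained
subjects, and every subject strictly below the cut is illiterate. The
published rule (trim 10%, cut the accuracy ranking) does not fully determine
the assignment; this operationalization makes low-performing outliers seed
the illiterate set while a trimmed high performer stays literate.

**Kernel similarity and desegregation.** Model similarity is the Gaussian
kernel exp(−‖η−η′‖²/σ²) on flattened (band × MI-interval position ×
motor-area channel) vectors, with unsupported cells filled with 0 and the
motor-area subset defaulting to C3/Cz/C4 plus FC3/FC4/CP3/CP4 where present.
When σ is unset it is the median pairwise distance among the vectors being
compared (distances at rounding-noise level are treated as zero, with σ
falling back to 1 — any σ then gives similarity 1). The desegregation curve
recomputes the group model with the 0, 1, 2, … worst-accuracy subjects
removed (truncating below 3 remaining) and reports each model's similarity
to the full-cohort model plus the pairwise similarity matrix.

## Synthetic cohorts

The generator emulates cue-paced MI trials: 1/f^α Gaussian background noise
(α = 1, unit variance, spectrum floored below 1 Hz) on every channel, plus
amplitude-modulated sinusoids with uniform random phase per trial.
An ERD plant runs an oscillator at the band center for the whole trial and
scales its amplitude by √(1 + depth·gain) inside the plant interval for the
plant's class, so the planted in-band power change *is* depth·gain — the
generator is its own oracle. A coupling plant injects a shared oscillator
into a pair with a fixed phase offset; the second channel mixes shared and
independent oscillators with weights (strength, 1−strength), so wPLI → 1 at
strength 1. Per-subject gains are log-normal (σ = 0.2 by default; 0 makes
subjects identical). Seeding uses `SeedSequence(seed, spawn_key=(subject,
stream))`, so cohorts are bit-reproducible and a subject's data do not
depend on cohort size or ordering.

Default study conditions: M = 9 subjects, 72 trials per class (144-trial
feature matrices), C = 22 channels at 250 Hz, 7 s trials, contralateral
mu-band plants of depth −0.5 in dT3 (C3 for right hand, C4 for left), 20 dB
in-band oscillation-to-background SNR. At 20 dB the noise floor shrinks a
recovered relative power change by s/(1+s) ≈ 0.99, keeping the generator's
oracle property within ~1%; `expected_zeta` reports the exact value.

What the generator does **not** emulate: volume conduction between channels
(each channel's background is independent), eye/EMG artifacts, trial-to-trial
non-stationarity beyond random phase, realistic head geometry. Passing
recovery tests therefore demonstrates the estimators and statistics are
correct, not that real recordings will behave this well; the Laplacian and
wPLI stages in particular face much harder conditions on real data.

## Validation sizes and known limitations

The acceptance benchmarks (in `migroup.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: ~102 random SPD
pairs (C ≤ 4) against a multi-start Nelder-Mead Rayleigh-quotient
maximization oracle; 500 null draws at 200 trials for the wPLI floor; 200
trials for ERD recovery; ≥ 1000 null cells for significance calibration; 3
null cohorts plus the canonical planted cohort for pFDR calibration/power;
and 20 cohorts each for group recovery and desegregation. These sizes are
the package's stated study conditions.

Known limitations:

- The trial-ensemble wPLI null floor means a single estimate at n = 200
  trials exceeds 0.15 with probability ~5–6% even with no coupling
  (|Z|·√(π/2n) ≈ 0.079·|Z| for unit-magnitude phasors; heavier-tailed
  coefficient magnitudes raise the exceedance further). Interpret wPLI maps
  against this floor or the Monte-Carlo null, not against 0.
- Divisive baseline normalization of wPLI amplifies null-pair noise (small
  random denominators); subtraction mode is available.
- ζ-based class comparisons inherit baseline-estimation error as a shared
  offset (see the relevance section); per-cell raw p-values are optimistic
  on null data even though corrected discoveries stay controlled.
- The printed window-grid conventions give 61 positions for τ = 1 s at 90%
  overlap and 70 for τ = 0.1 s non-overlapping over 7 s; these counts follow
  from the stated convention and are the ones used throughout.
- GDF ingestion assumes the standard cue event codes (769/770, artifact
  1023) and epochs [−2, +5] s around the cue; recordings with other schemes
  need the codes remapped.
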