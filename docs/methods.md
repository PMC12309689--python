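# Methods

`frsa` implements frequency-domain representational similarity analysis
(fRSA) for detecting categorical structure in continuous responses to a
continuum of two-interval rhythms, together with the behavioral
inter-tap-interval (ITI) pipeline, a prototype-similarity analysis, and a
synthetic-data generator that gives every stage a known ground truth.
This note records the models, the parameters that matter, the numerical
choices, and what the tests do and do not establish.

## The experimental world being modelled

A two-interval rhythmic pattern of fixed duration T (default 0.75 s)
contains two tone onsets per cycle, at 0 and r·T, where
r = IOI1/(IOI1+IOI2) is the interval ratio: r = 0.50 is the isochronous
1:1 rhythm and r = 2/3 the 2:1 rhythm. A condition continuum places n
(default 13) ratios linearly between these endpoints; each condition is
presented as the pattern seamlessly looped (default 30 cycles, 22.5 s),
so the third tone of a cycle is the first tone of the next. Human
listeners do not reproduce this continuum faithfully: produced and
represented rhythms gravitate toward a small set of category prototypes,
with a category boundary partway along the continuum.

## Frequency tagging

Because the stimulus repeats at f0 = 1/T (1.333 Hz for T = 0.75 s), any
phase-locked response concentrates at f0 and its integer harmonics. The
toolkit computes the FFT of the trial-averaged signal (no windowing; an
integer number of cycles guarantees every harmonic lands on an exact
frequency bin, asserted at runtime with tolerance 1e-6·df). Coefficients
are divided by the number of samples, so a unit-amplitude exact-bin
cosine has magnitude 0.5; the convention cancels in every correlation
and z-score downstream and is pinned by tests.

Response significance at a harmonic is assessed with a local-noise
z-score: baseline = the eight bins at offsets ±2..±5 around the bin
(immediately adjacent bins skipped against residual leakage),
z = (x − mean(baseline)) / SD(baseline). The **sample** SD (n−1) is
used; the choice is not dictated by the procedure's definition and the
tests pin it explicitly. z > 3.09 (one-tailed P < 0.001) marks a
significant harmonic, and only the unbroken run of significant harmonics
starting at f0 is retained as frequencies of interest (FOIs) — 6
harmonics up to 8 Hz for EEG-like data (above which alpha-band activity
contaminates the spectrum), 12 harmonics up to 16 Hz for tapping
signals.

## RSMs and categorical models

Per condition, the real and imaginary FFT coefficients at the FOIs are
concatenated (FOI-major, re before im, channels innermost) into a
feature vector of length n_foi × 2 × n_channels; the response RSM is the
Pearson correlation of these vectors across all condition pairs. Scalar
summaries (mean produced ITI ratio) give a `1 − |difference|` RSM, as
does the stimulus itself (the acoustic RSM over the ratios r). Time-domain
RSMs correlate the demeaned per-condition average cycles. All RSMs are
symmetric with unit diagonal; undefined entries (zero-variance input) are
stored as NaN and excluded pairwise downstream, with a count surfaced on
the RSM object.

Theoretical two-category models are binary RSMs with entry 1 iff both
conditions fall on the same side of a boundary; boundaries whose
categories span fewer than 2 conditions are excluded, giving
n − 2·min_span + 1 models (10 for n = 13). A model's boundary is
reported on the ratio scale as the midpoint between the flanking
condition ratios.

## Inference

The test statistic is Spearman's partial correlation between the
strictly-lower triangles (fixed column-major order, 78 entries for
n = 13) of the response RSM and each categorical model, partialing out
the acoustic RSM; the best-fitting model is the one with the highest
coefficient (ties broken toward the central boundary, logged). The
partial correlation is computed as the Pearson correlation of rank
residuals after least-squares regression on the covariate ranks; the
vectorized permutation engine uses the algebraically identical
single-covariate identity r_xy·c = (r_xy − r_xc·r_yc)/√((1−r_xc²)(1−r_yc²))
and is asserted equal to the residual route and to an independent
library implementation in the tests.

Permutation tests shuffle the lower-triangle entries of the response RSM
(not rows/columns — this matches the stated procedure verbatim; it
breaks matrix-symmetry semantics, which is why all statistics operate on
the triangle vector). Individual test: 5000 iterations, statistic = max
over models of the partial rho. Group test: 10000 iterations, statistic
= mean over participants of each one's best-model rho, every
participant's triangle shuffled independently per iteration. p values
use the add-one estimator (b+1)/(n+1), consistent with reported floors
of 1/(n+1); Bonferroni correction multiplies by the number of candidate
models (10). Boundary consistency across participants is summarized by a
percentile bootstrap CI of the median boundary ratio (participants
resampled with replacement, default 10000 draws). Cross-response
agreement uses (a) partial Spearman between two response RSMs given the
acoustic RSM with the same permutation scheme, (b) Fisher-z-transformed
10-model fit profiles correlated within participant and tested against
zero with a one-sample t test, and (c) paired t tests on
Fisher-transformed best-model coefficients. Bayes factors are out of
scope; the results JSON carries a null placeholder.

The `CategoricalRSA` model object wraps this machinery statsmodels-style:
constructed from per-participant response RSMs plus the acoustic RSM,
`fit()` returns a results object carrying per-participant fits, group
permutation p, boundary bootstrap, and a `summary()` table.

### Known property: conservativeness under structured nulls

Shuffling triangle entries tests exchangeability. Under a null in which
the response faithfully tracks the stimulus, the RSM retains smooth
acoustic-driven structure that rank-partialing does not remove exactly
(the acoustic triangle has heavy ties — only 12 distinct values among 78
for the linear grid). Shuffles destroy that smoothness and produce a
*broader* max-over-models null than the structured observed statistic,
so the test under-rejects: on 200 null-simulated tapping participants
the measured rejection rate at α = 0.05 is 0, below the nominal band
(the corresponding acceptance test is deliberately left failing as a
record of this property). With fully exchangeable pure-noise RSMs the
test is exact and calibrated (verified: rejection rate within
[0.02, 0.08] over 200 replicates). The error direction is conservative —
no inflation of false positives — and planted categorical structure is
recovered with the group p at its floor in 20/20 seeded replicates.

## Behavioral (ITI) pipeline

Tap onsets are cleaned by dropping any onset closer than 30 ms to the
previously retained onset (greedy left-to-right). The participant's mean
tap−tone asynchrony, pooled over all trials and conditions *after*
cleaning (the only plausible order), is subtracted from every onset;
taps whose residual distance to the nearest tone exceeds 80 ms are
excluded. Per cycle, the two tones of the cycle and the first tone of
the next are matched to their nearest taps; when one tap is nearest to
two tones the pairing with the smaller asynchrony wins and the losing
tone is unmatched (conflict handling is not dictated by the procedure;
fixed here and tested). A cycle with any unmatched tone is excluded;
otherwise ITI ratio = (tap2 − tap1)/(tap3 − tap1). The final cycle needs
the tone closing the loop, so a sequence's last cycle is only valid if a
tap matches the end-of-sequence time.

Produced-vs-stimulus ratio curves are fitted with a 4-parameter logistic
y = a + (b−a)/(1+exp(−k(x−x0))) — free asymptotes, because produced
ratios plateau near the category attractors rather than at fixed values —
and with a line, both by least squares from five deterministic starting
points. Model comparison uses leave-one-participant-out cross-validation
(held-out R² per fold) and a Wilcoxon rank-sum test on the two sets of
per-fold R²; rank-sum (not signed-rank) is used although folds are
paired, matching the stated procedure. Deviation of the pooled produced
ratios from uniformity is tested with a χ² goodness-of-fit statistic
over 13 equal bins spanning the stimulus range (df = 12); values outside
the range count toward the nearest edge bin.

## Prototype analysis

76 two-impulse templates with ratios equally spaced on [0.50, 0.84] are
rendered as impulse trains (0.75-s pattern × 30 cycles) and fingerprinted
by their magnitudes at the FOIs. A template at ratio r has magnitude
proportional to 2|cos(πkr)| at harmonic k (closed form; deviations from
the FFT route < 1e-8 across the whole set). The grid endpoint 0.84 sits
in tension with the motor-constraint rationale usually given for
excluding shorter intervals (0.84 × 750 ms = 120 ms); the stated
endpoints are used as-is. Templates are noiseless, so raw (uncorrected)
template magnitudes are correlated against noise-corrected response
magnitudes.

Response magnitudes are noise-corrected per FOI by subtracting the mean
of the same eight local-baseline bins (negative values kept). Because
this correction is linear in the magnitude spectrum, averaging
per-participant corrected vectors equals correcting the average
spectrum, so the bootstrap operates on per-participant corrected FOI
vectors: each of 1000 iterations resamples participants with
replacement, averages their vectors, Pearson-correlates the average with
every template fingerprint per condition, and stores the argmax template
ratio. All-constant vectors mark the iteration undefined (counted, not
stored).

The on-stimulus test asks whether this distribution concentrates on the
stimulus ratio: the in-window spans the midpoints to the neighboring
conditions (edge conditions use the symmetric half-step), the out-region
is the rest of the 0.34-wide template range, and the index is
n_in/width_in − n_out/width_out. The full bootstrap is re-run 500 times;
a condition is flagged off-stimulus when the index is negative in more
than 95% of runs after Bonferroni correction over the 13 conditions
(reported as p = add-one proportion of runs with index ≥ 0, ×13).

Pooled peaks: best-template ratios are pooled over the conditions of
each category (split at the fRSA median boundary), a Gaussian KDE
(Silverman bandwidth, recorded in the output) is evaluated on a 512-point
grid over the template range, and local maxima above 10% of the mean
grid density are peak candidates. A distribution degenerate at a single
template is treated as a peak at that template (bandwidth 0). Each peak
is tested by contrasting counts in a window one condition-grid-step wide
against flanks of half that width on each side, over 500 re-runs of the
bootstrap; p = add-one proportion of runs with index ≤ 0 — the stated
"larger than zero" direction would give p ≈ 1 for a true peak, so the
only usable direction is implemented — Bonferroni-corrected by the
number of peaks tested.

## Synthetic data

The generator states one world and keeps it fixed:

| parameter | default | meaning |
|---|---|---|
| continuum | 13 ratios, 0.50–2/3, T = 0.75 s, 30 cycles | stimulus design |
| boundary_after | 5 | true category split (boundary ratio 0.5625) |
| attractors | 0.53 / 0.63 | produced-rhythm prototypes per category |
| warp_strength | 0.8 | produced r = (1−w)·r_stim + w·attractor |
| timing_sd_s | 0.010 | per-tap Gaussian jitter |
| asynchrony_mean_s | −0.030 | constant anticipation of the pacing tone |
| miss_rate / extra_rate | 0.02 / 0.02 | per-tap deletion / per-cycle insertion |
| trials | 3 tapping / 6 EEG per condition | |
| n_participants | 18 | |
| fs | 256 Hz | |
| kernel | gamma-shaped, peak 100 ms | EEG impulse response |
| noise_amp / alpha_amp | 7.0 / 4.0 | 1/f and 8–12-Hz noise SD multipliers |

The attractor values are non-integer softened prototypes so that
prototype-recovery tests have ground truth away from the trivial 0.5 and
2/3; the −30-ms anticipation and 10-ms jitter are typical values for
paced finger tapping by non-musicians. EEG-like trials convolve the
warped impulse train with the kernel **circularly** (the steady state of
a seamless loop), so the noiseless response is exactly periodic and its
spectrum exactly harmonic — the onset transient of real recordings is
deliberately absent. Channel topography is a fixed frontocentral-maximum
gain profile over a 64-label 10-10 montage; noise is independent 1/f
plus band-limited alpha per channel and trial, with no spatial
covariance. The noise amplitudes were calibrated once so that the
grand-average FOI z-scores at the stated world (18 participants, 13
conditions, 64 channels) land in the single digits to low tens, the
regime in which frequency tagging is informative but not trivial; they
were not revisited afterwards.

What a green recovery test establishes: the pipeline recovers planted
categorical structure, boundaries, and attractor ratios from data with
realistic timing noise, misses, and spectral noise. What it does not:
robustness to artifacts the generator omits — non-stationary noise,
channel covariance, onset transients, drifting asynchrony, or
participant heterogeneity in boundary position.

Simulators are bit-reproducible given (seed, participant_seed); every
resampling routine accepts a local seed and the pipeline derives all of
its seeds from one config value.

## Numerical choices

- Zero-phase (forward-backward) Butterworth filtering: group delay would
  distort time-domain RSM correlations; attenuation is the squared
  magnitude response, asserted analytically in tests.
- Downsampling is plain decimation; a warning is emitted if no low-pass
  was recorded on the signal.
- Epoch boundaries use round-to-nearest sample; at 256 Hz the 0.75-s
  cycle is exactly 192 samples.
- Ratios are compared with tolerance 1e-9; printed values elsewhere are
  rounded presentations of the exact linear grid.
- Pearson of feature vectors equals Pearson of the demeaned time courses
  exactly when the concatenated coefficient vector is mean-free
  (Parseval); for generic band-limited signals the two differ by the
  feature-mean term. The equivalence test synthesizes mean-free
  coefficient vectors, the regime where the identity is exact.
- `|rho| = 1` entries are clipped at 1 − 1e-12 before Fisher transforms,
  with a warning; zero-variance t-test differences report p = 1 (zero
  mean) or p = 0 (nonzero mean) by convention, logged.

## Limitations

- EDF/BrainVision acquisition formats are not read; recordings arrive as
  delimited text, `.npy`, or WAV. Acquisition preprocessing (artifact
  removal, re-referencing, channel interpolation) is out of scope.
- The permutation test's calibration under structured nulls is
  conservative (see above); its p values are trustworthy for rejection,
  not for uniformity under every null.
- Only two-interval prototypes and two-category models are implemented;
  distance measures other than Pearson/`1 − |diff|` are intentionally
  absent.
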