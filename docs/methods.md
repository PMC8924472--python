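# Methods

## Synthetic cohorts

Each simulated trial is pink noise plus a common evoked response, per
electrode and participant:

x(t) = n₁/f(t) + g·λₑ·A·exp(−(t−μ)²/2σ²) + g·λₑ·code(t)

where n₁/f is 1/f noise (spectral exponent 1.0 by default, per-trace SD
`noise_sd` = 10 µV, synthesized by spectral shaping of white noise), A = 5 µV
is the ERP amplitude with latency μ = 150 ms and width σ = 40 ms, λₑ ∈ [0.3, 1]
are fixed spatial loadings, and g ~ lognormal(0, 0.25) is a per-participant
gain (unit median, strictly positive) that makes decodability — and, through
the RT link, reaction time — vary across participants. Epochs span −200 to
+1000 ms; the default sampling rate is 250 Hz for desk-scale work (1000 Hz is
supported; window sample counts scale with fs).

The category codes are constructed so that exactly one feature family is
informative:

- **mean** — a sustained offset ∝ category index under a flat-top (tanh-edged)
  envelope spanning the ERP. A peaked envelope would vary within a 50 ms
  window and leak into window variance; the plateau keeps variance matched.
- **variance** — extra zero-mean noise inside the ERP envelope with SD
  multiplier 1 + es·category; means match by construction.
- **frequency** — a fixed-amplitude sinusoid with random phase per trial and
  category-specific frequency in 10 Hz steps (10, 20, … Hz). The spacing must
  be resolvable within one 50 ms window; the random phase keeps the window
  mean uninformative and the fixed amplitude keeps variance matched.
- **multiscale** — three oscillatory bursts at fixed latencies around the ERP
  with category-specific dyadic duration 2^(c+2) samples, per-burst energy
  normalized so total added variance matches across categories. The class
  difference is *which temporal scale* carries the waveform; wavelet
  coefficients see it as a mean shift, while window mean and variance are
  (approximately) blind to it. The bursts are deterministic (fixed sign and
  latency) because the pairwise LDA decodes class-mean differences: random-
  sign bursts would put the code purely in coefficient variance, which a
  linear discriminant cannot exploit.

Reaction times: participant mean RT = intercept − slope·g + N(0, noise_sd²)
(defaults 1146 ms, 200 ms per unit gain, 50 ms); per-trial RTs are jittered
around the participant mean with the same SD (the trial-level spread is not
separately parameterized) and floored at 100 ms.

What the generator does *not* emulate: volume conduction/dipole geometry,
artifacts, autocorrelated inter-trial structure, or realistic RT
distributions (a single Gaussian around the participant mean). Passing
tests therefore demonstrate correctness and calibration of the pipeline,
not expected effect sizes on real recordings.

## Features

All 26 features are computed per trial and electrode inside 50 ms windows
stepped at 5 ms by default (w = round-half-up(width·fs/1000) samples, ≥ 8;
a window around center c covers samples c−⌊w/2⌋ … c−⌊w/2⌋+w−1, and only
centers where the full window fits are used). Trials are baseline-corrected
(mean of t < 0 removed per trial and electrode) once before extraction.

Parameter choices where the field convention was the deciding factor:

- Lempel-Ziv: binarize at the window median with ties mapping to 1
  (deterministic, scale-free), then count phrases of the exhaustive (LZ76 /
  Kaspar-Schuster) parsing, no length normalization.
- Katz FD uses amplitude-only path lengths (L = Σ|Δx|), which keeps it
  invariant to amplitude scaling; Higuchi uses kmax = 8 (≈ w/5 for w = 50).
- Hurst: rescaled-range over dyadic segment lengths (≥ 8 samples) with the
  Anis-Lloyd small-sample correction, clipped to [0, 1]. Needs w ≥ 16, so at
  250 Hz the 50 ms window (13 samples) is too short for this feature —
  use ≥ 320 Hz or wider windows.
- Entropies: m = 2, r = 0.2·SD, Chebyshev distance; SampEn excludes
  self-matches (capped at ln B + ln 2 when no m+1 matches exist), ApEn is the
  Pincus φ-difference.
- Spectral summaries use a raw rectangular-window periodogram of the
  mean-removed window; power/phase "at the median frequency" are read from
  the discrete bin nearest that frequency.
- Autocorrelation lag defaults to 10 ms (round(10·fs/1000) samples).
- Wavelet: Symlet-2, 5 levels, half-point symmetric boundary extension (the
  Matlab wavedec convention). D1…D5 of a 50-sample window total 57
  coefficients; the A5 approximation (4 more) is off by default and exposed
  via a flag, matching the printed 57-coefficient convention. Windows
  shorter than 32 samples reduce the level count with a warning.
- Kurtosis is raw (not excess); variance uses the n−1 denominator.
- Degenerate (zero-variance) windows return documented sentinels (0 for
  skewness/kurtosis/entropies/autocorrelation/Hjorth, 1 for fractal
  dimensions, 0.5 for Hurst) and are flagged in tensor metadata — never NaN.

## Reduction, selection, decoding

All three PCA stages are centering-only (no variance scaling), fit
exclusively on the training trials of the current fold and applied with the
training means/loadings to training and test alike. Components carry a
deterministic sign (largest-magnitude loading entry positive). When the
training rank is below the requested component count, the available rank is
kept and loadings are zero-padded so downstream shapes hold (warned).
Stage-3 equalization pools all training trials regardless of label
(unsupervised PCA).

Scorer details: mutual information uses equal-frequency binning with 8 bins;
mRMR scores are the reverse of the greedy selection order; ReliefF samples
50 instances with 10 nearest hits/misses under the run seed; the lasso
scorer picks λ from 10⁻³…10¹ (7 points) by internal 3-fold validation and
breaks exact ties (zeroed coefficients) by Fisher score; the Laplacian score
uses a 5-NN heat-kernel graph (negated so higher is better); cfs is
1 − mean |r| with the other columns. k = 5 features are selected by default
(configurable). Ten of the seventeen published selection algorithms the
pipeline is meant to host are complex cited optimizations and are not
re-implemented; the registry accepts them as plug-ins with the same
signature.

LDA uses the pooled within-class covariance shrunk toward the scaled
identity, S ← (1−γ)S + γ(tr S/p)I with γ = 0.05 — necessary because the
electrode count can approach per-fold trial counts — and class-frequency
priors. Accuracy is the pooled proportion correct over all test trials
across folds (robust to unequal fold sizes), averaged over all category
pairs per participant; chance is 0.5. Pairs are decoded using only the two
categories' trials. Everything is a pure function of (data, seed).

## Statistics

The JZS Bayes factor integrates the g-prior representation of the Cauchy
effect-size prior (scale r = √2/2, the common toolbox default) by adaptive
quadrature; the unpaired form is used for the post-vs-baseline comparison
(baseline = per-participant mean pre-stimulus accuracy), and no multiplicity
correction is applied to Bayes factors. Decoding-curve parameters are
computed post-stimulus per participant; "onset" is the first window whose
accuracy exceeds chance for ≥ 5 consecutive windows (25 ms at the 5 ms
step) — a sustain rule, since an instantaneous crossing is noise-dominated.

The brain-behavior permutation test shuffles the RT vector across
participants (1000 seeded permutations, sampled uniformly with replacement)
and evaluates the tail in the observed direction with add-one smoothing.
Because the direction is selected after seeing the data, that raw p is
uniform on (0, ½] under the null; it is therefore doubled (capped at 1)
before FDR — without this, any FDR procedure that assumes uniform null
p-values estimates π₀ ≈ 0 and flags every window, including on data with no
RT link at all (we verified this failure directly). q-values are Storey
pFDR with λ = 0.5 fixed, falling back to Benjamini-Hochberg when no
p-value exceeds λ (π₀ inestimable on short, strongly significant series);
windows with q < 0.05 are significant.

## Calibration suites and problem sizes

The committed calibration fixture (`src/eegdecode/data/calibration.json`)
fixes the study conditions of the property suites, chosen once by a pilot
sweep: specificity cohorts of 5 participants, 2 categories x 24 trials,
8 electrodes at 250 Hz with effect sizes 1.0 (mean, variance, multiscale)
and 2.0 (frequency); null-calibration cohorts of 10 participants,
4 categories x 30 trials, 16 electrodes; behavior-recovery cohorts of 16
participants with effect size 1.5 and RT link (slope 400 ms per unit gain,
noise 20 ms) — rank-correlation power at 10 participants is marginal once
the permutation floor (p ≥ 2/(N+1)) and FDR are honest, so the recovery
suite uses 16. The suites analyze a 20 ms window step at 250 Hz (58 windows
per epoch), the package's desk-scale analysis resolution; the 50 ms / 5 ms
default mirrors the full-scale convention.

The null chance band is the central 95% binomial band for the group-mean
accuracy computed on the number of *distinct* trial predictions
(participants x trials): each trial is re-used in n_categories − 1 pairs, so
the naive participants x pairs x trials count understates the variance of
pair-averaged accuracies (empirically ~81% coverage instead of 95%).

## Known limitations

- The unpaired post-vs-baseline Bayes test inherits dependence across
  windows through the shared baseline: on null data the strong-evidence
  rate fluctuates around ~0.5% per cohort set and can exceed 1% for
  unlucky baselines.
- With ~10 participants, the permutation test's smallest attainable
  two-sided p is 2/(N+1); genuinely strict "zero false positives
  anywhere" guarantees are not achievable by any calibrated test, and the
  recovery suite asserts rates, not absolutes.
- Entropy/fractal/LZ extractors are loop-based per window and dominate
  extraction cost at full scale; moments, spectral, Hilbert, wavelet and
  cross-correlation are vectorized.
- The Hurst feature requires ≥ 16-sample windows (not available at 250 Hz
  with 50 ms windows).
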