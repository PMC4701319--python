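# Methods

## Pipeline

Given a multichannel scalp EEG recording (channels × samples, microvolts,
10–20 labels), the pipeline is:

1. **Band limiting.** A zero-phase second-order IIR notch at the mains
   frequency (default 50 Hz, quality factor Q = 30), then a zero-phase
   4th-order Butterworth band-pass, 0.5–64 Hz. Zero-phase (forward–backward)
   filtering is used so group delay cannot shift epochs between the raw and
   denoised branches that the scoring compares; filter family, order, Q and
   corners are configurable.
2. **Epoching.** Non-overlapping 256-sample epochs (1 s at 256 Hz) per
   channel; a trailing remainder is discarded with a warning.
3. **Candidate scoring.** Each of the 45 orthogonal candidates denoises
   each epoch (below); the score is the Pearson cross-correlation between
   the band-limited epoch and its denoised version. Undefined correlations
   (constant epochs) are stored as NaN, counted, and excluded from pools.
4. **Region pooling and selection.** Scores pool over each scalp region's
   channels (frontal 7, temporal 4, parietal 3, occipital 2, central 3).
   Per region, a one-way ANOVA across the 45 wavelet groups is followed by
   Duncan's multiple range test; the winner is the highest mean score, ties
   broken lexicographically by name. A two-way ANOVA (region × wavelet,
   Type II sums of squares) is available as a diagnostic.
5. **Band power.** After denoising with the selected wavelet, each channel's
   5-level MRA components D2..D5, A5 are mapped to the clinical bands
   (lower gamma, beta, alpha, theta, delta) and the relative power of each
   band is its component energy divided by the summed energy of those five
   components, × 100. D1 (64–128 Hz) is excluded from the denominator: the
   analysis band stops at 64 Hz and D1 is treated as higher gamma plus
   residual noise. Regional tables average per-channel RP by default (each
   row still sums to 100%); pooling raw component powers across the
   region's channels first is available behind a flag.

## Wavelet bank and transforms

The bank is db1–db20, sym1–sym20, coif1–coif5 — 45 entries. Symlets
conventionally begin at order 2, so `sym1` is defined as an alias of the
Haar wavelet (= db1), and sym2/sym3 coincide with db2/db3 by construction
of the least-asymmetric family; the bank therefore contains a few
duplicate filter pairs under distinct conventional names, which is
intentional (the bank is defined by its names) and exploited by a cache so
aliases are computed once. Filter coefficients come from PyWavelets and
are validated at load time against the orthonormal scaling-filter
invariants (sum h = √2, unit norm, even-shift orthogonality, sum g = 0).
The high-pass filter follows the quadrature-mirror convention
g[n] = (−1)ⁿ h[L−1−n].

Boundary handling is selectable per call: `symmetric` half-point extension
(default — no wrap-around transients on real epochs) or `periodization`
(exactly orthonormal on even lengths, so coefficient energy equals signal
energy; used by the Parseval checks and by the wavelet-structured
generator, where exact coefficient counts matter). Both modes round-trip
to 1e-10. Decomposition depth is limited by two rules: the signal must be
at least one filter length, and at least 2^levels samples long; coarse
levels of long filters rely on the boundary extension, which is standard
for 256-sample epochs with 5 levels.

## Denoising

Per epoch: 5-level DWT; each detail set cD_k is soft-thresholded with its
own threshold; cA₅ is never touched; inverse DWT. Thresholds minimise
Stein's unbiased risk estimate over the exhaustive candidate set
{|c_i|/σ} (an O(n log n) sweep, matched to a brute-force oracle in the
tests). A hybrid rule ("heursure": universal threshold σ√(2 ln n) when the
coefficients look too sparse for SURE) and outright zeroing of D1 are
selectable.

The noise scale σ is the robust MAD estimate median(|cD|)/0.6745. Its
scope is a genuine design choice with no single right answer:

* `sigma_scope="level"` (default) re-estimates σ from each level's own
  coefficients. The median is robust when genuine structure occupies a
  minority of a level's coefficients — the regime of transient/sparse
  activity — and adapts to coloured noise. This scope is what makes the
  selection experiment discriminative: a mismatched wavelet smears
  structure across many coefficients, inflates the level's σ and threshold,
  and loses signal, whereas the matched wavelet concentrates structure in
  few coefficients that survive.
* `sigma_scope="finest"` estimates σ once from cD₁ and shares it across
  levels. Use it when sustained narrowband oscillations fill entire levels
  (e.g. a strong continuous alpha rhythm): there the per-level median sits
  on the signal itself and the level would be shrunk away. The
  single-epoch denoising example in the test suite demonstrates both
  behaviours explicitly.

Soft thresholding never increases coefficient magnitude, so under
periodization the denoised epoch's energy never exceeds the input's.

## Statistics

* Kolmogorov–Smirnov normality check against a normal with the sample's
  mean and SD (asymptotic p; approximate because the parameters are
  estimated, adequate as a screen at the pool sizes involved).
* Levene's homoscedasticity test, classic mean-centered form.
* One-way ANOVA with an explicit between/within decomposition (the within
  mean square and degrees of freedom feed Duncan's test); identical-value
  groups raise a zero-variance error rather than reporting an infinite F.
* Duncan's multiple range test: means sorted descending; for a span of p
  ordered means the critical range is R_p = q(1−(1−α)^(p−1); p, df) ·
  √(MSE/n_h), with n_h the harmonic mean group size and q the studentized
  range quantile computed numerically from `scipy.stats.studentized_range`
  (validated against published 5% Duncan tables at df 10/20/∞ to ~2e-3).
  Homogeneous subsets come from a widest-first sweep in which a range
  inside a non-significant stretch is never tested (the standard
  protection), then letters are assigned to the maximal stretches.

## Synthetic data

The generator emulates the recording conditions the pipeline targets — it
is the test bed, not a biophysical simulation.

* **Background**: per channel, a sum of band-limited Gaussian carriers
  (0.5–4, 4–8, 8–16, 16–32, 32–64 Hz), each normalised to unit RMS and
  scaled by `amplitude · weight_band · (f_c/2 Hz)^(−exponent/2)`. Defaults:
  fs 256 Hz, 60 s, amplitude 10 µV, unit band weights, 1/f exponent 1.0 —
  so the default spectrum falls as 1/f with ~10 µV RMS slow activity,
  within the few-to-100 µV range of scalp EEG. Regional modifiers colour
  the mix (occipital alpha ×2.0, parietal alpha ×1.5, frontal delta ×1.3 /
  theta ×1.2), giving region-wise analyses realistic structure.
* **Artifacts**: ocular — Poisson blinks (0.2/s) of smooth 0.2–0.5 s
  positive lobes, ~75 µV; muscle — Poisson bursts (0.1/s) of 64–127 Hz
  noise, 10 µV RMS, Hann-windowed; line — 50 Hz sinusoid, 5 µV, phase
  shared across channels. All additive; zero amplitudes give the identity.
* **Wavelet-structured signals**: 5% of the periodized 5-level
  decomposition coefficients of a 256-sample epoch are drawn as
  10·N(0, 1), the rest zero; the clean signal is the inverse transform and
  white noise is added at the requested SNR. The generating wavelet is the
  ground-truth optimum for recovery experiments.

All randomness flows through one seeded NumPy generator; identical
configurations are bit-identical. What the generator does **not** emulate:
volume conduction and inter-channel correlation (channels are independent
except the mains phase), non-stationarity across the recording, cardiac
artifacts, electrode drift or impedance changes. Passing tests therefore
show the machinery is correct and the selection experiment is recoverable
under controlled conditions — not that any particular wavelet is optimal
for real recordings.

## Problem sizes and numerical choices

The selection-recovery experiment runs at 19 channels × 10 epochs × 45
wavelets per seed, 20 seeds, SNR 10 dB — about one minute on one CPU — and
asks the generating wavelet to rank in the top 3 of the mean ordering in at
least 80% of runs. Null calibrations use 100 seeds of 45 equal groups
(n = 20). Transform invariants run over all 45 wavelets (round-trip 1e-8,
Parseval 1e-8 relative under periodization). Studentized-range quantiles
are cached by (α, span, df) since they are the only expensive statistic.
Degenerate inputs raise typed errors (constant epochs → undefined
correlation; all-zero powers → undefined RP; zero within-variance → ANOVA
error) rather than NaN propagation.

## Known limitations

* The XCorr criterion compares the denoised epoch with the *noisy*
  band-limited epoch, so it rewards signal retention more than noise
  removal; wavelets with very similar filters (the sym/db low-order
  aliases) produce near-identical scores by construction.
* Relative power is wavelet-based (dyadic edges at 8–16 Hz for alpha, etc.),
  not an FFT band integral; the 12–16 Hz part of the alpha component
  overlaps what some conventions call low beta.
* Gamma is lower gamma (32–64 Hz) only; content above 64 Hz is outside the
  band-limited range and treated as noise.
* EDF files are read (via MNE) but not written; the text interchange format
  is CSV + YAML sidecar.
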