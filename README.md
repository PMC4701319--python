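# mwtselect

Region-wise **mother-wavelet selection** for multichannel EEG, with
SURE soft-threshold denoising and sub-band relative power.

Discrete-wavelet analysis of EEG — denoising, decomposition, sub-band
feature extraction — starts from a choice that is usually made by habit:
the mother wavelet. `mwtselect` makes that choice empirical. It scores a
bank of 45 orthogonal candidates (Daubechies db1–db20, Symlets sym1–sym20,
Coiflets coif1–coif5) against the recording itself and reports, for each
scalp region of the 10–20 montage, which basis represents the signal best,
together with the statistical evidence for the ranking. It is written for
researchers processing scalp EEG (cognitive tasks, clinical screening) who
want the wavelet choice to be data-driven and auditable.

## Method

For each channel the band-limited recording (50 Hz notch, 0.5–64 Hz
band-pass) is cut into non-overlapping 256-sample epochs. Every candidate
wavelet `w` denoises every epoch: a 5-level DWT, soft thresholding of the
detail coefficients cD₁..cD₅ with level-dependent thresholds chosen by
minimising Stein's unbiased risk estimate (SURE)

    SURE(t) = n − 2·#{ |cᵢ|/σ ≤ t } + Σᵢ min(|cᵢ|/σ, t)² ,

σ estimated by the median absolute deviation, and inverse DWT. The fitness
of `w` on an epoch X with denoised version Y is the Pearson
cross-correlation

    XCorr(X, Y) = Σ (X−X̄)(Y−Ȳ) / √( Σ(X−X̄)² · Σ(Y−Ȳ)² ) ∈ [−1, 1].

Scores are pooled over the channels of each scalp region (frontal,
temporal, parietal, occipital, central), compared across the 45 wavelet
groups by one-way ANOVA, and ranked; Duncan's multiple range test marks
the runners-up that are statistically indistinguishable from the winner at
α = 0.05.

A 5-level decomposition at 256 Hz tiles the spectrum dyadically
(D1 64–128 Hz: higher gamma/noise, D2 32–64: lower gamma, D3 16–32: beta,
D4 8–16: alpha, D5 4–8: theta, A5 0–4: delta), and the relative power of
band b is

    RP_b (%) = 100 · P_b / Σ_{b' ∈ {δ,θ,α,β,γ}} P_b' ,

with P the energy of the reconstructed MRA component (D1 is excluded from
the denominator as noise).

Because public EEG recordings of this protocol are not available, the
package ships a first-class synthetic generator: 19-channel 10–20
recordings with 1/f-weighted band-limited background, ocular/muscle/line
artifacts, and *wavelet-structured* signals (sparse coefficients in a known
basis plus noise) that give selection experiments a ground truth.

## Worked example

`examples/03_select_wavelet.py` generates a recording whose epochs are
sparse in the sym9 basis at SNR 10 dB and runs the full selection:

```
frontal: best wavelet 'sym9' (mean XCorr 0.9687); not significantly different: coif3, db4, sym5, sym6
temporal: best wavelet 'sym9' (mean XCorr 0.9694); not significantly different: coif2, coif3, db4, ...
parietal: best wavelet 'sym9' (mean XCorr 0.9677); ...
occipital: best wavelet 'sym9' (mean XCorr 0.9685); ...
central: best wavelet 'sym9' (mean XCorr 0.9688); ...

frontal top five by mean XCorr: ['sym9', 'sym5', 'sym6', 'db4', 'coif3']
frontal ANOVA: F = 6.43, p = 9.66e-35
```

The generating wavelet wins every region; the Duncan subsets name the
wavelets whose mean score cannot be distinguished from the winner's.
`examples/04_band_power.py` prints the per-region relative-power table of a
denoised synthetic recording (rows sum to 100%; the generator's posterior
alpha boost is visible as occipital alpha 11.8% vs frontal 3.9%).

The same pipeline is scriptable from the shell:

```bash
mwtselect simulate --seed 3 --out runs/sim
mwtselect select --input runs/sim/recording.csv --out runs/sel
mwtselect denoise --input runs/sim/recording.csv --wavelet sym9 --out runs/den
mwtselect bandpower --input runs/sim/recording.csv --wavelet sym9 --out runs/bp
```

Inputs are EDF or a channels × samples CSV/TSV with a `{fs, labels}` YAML
sidecar; every run directory records the resolved config, package version
and seed.

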