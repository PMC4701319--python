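"""SURE soft-threshold denoising of a single noisy epoch.

Builds one 256-sample epoch of a 10 Hz alpha-band oscillation buried in
white noise (SNR 20 dB), denoises it with db4 using the shared
finest-level noise estimate, and reports the per-level thresholds and how
much closer the denoised epoch is to the clean oscillation.
"""

import numpy as np

from mwtselect import denoise_epoch_with_report, get_wavelet, xcorr

rng = np.random.default_rng(0)
fs = 256.0
t = np.arange(256) / fs
clean = 50.0 * np.sin(2 * np.pi * 10.0 * t)  # microvolts
noise_sd = np.sqrt(np.mean(clean**2) / 100.0)  # SNR 20 dB
noisy = clean + rng.standard_normal(256) * noise_sd

w = get_wavelet("db4")
denoised, report = denoise_epoch_with_report(noisy, w, levels=5, sigma_scope="finest")

print(f"wavelet {report.wavelet}, rule {report.rule}")
for k, (t_k, s_k) in enumerate(zip(report.thresholds, report.sigmas), start=1):
    print(f"  level cD{k}: sigma = {s_k:7.3f} uV, threshold = {t_k:7.3f} uV")
print(f"correlation with clean signal: noisy {xcorr(noisy, clean):.4f}"
      f" -> denoised {xcorr(denoised, clean):.4f}")
print("(a higher denoised correlation means the shrinkage removed noise"
      " without flattening the alpha oscillation)")
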