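"""Sub-band power and relative spectral power from the MRA components.

After denoising, the 5-level decomposition of a 256 Hz signal maps its
reconstructed components onto the clinical EEG bands (A5 delta 0-4 Hz, D5
theta 4-8, D4 alpha 8-16, D3 beta 16-32, D2 lower gamma 32-64).  D1
(64-128 Hz) is higher gamma plus residual noise and is excluded from the
relative-power denominator, which covers the 0.5-64 Hz band-limited range:

    RP_band (%) = 100 * P_band / sum(P over {A5, D5, D4, D3, D2})

with P the sum of squared samples of the reconstructed component.  Powers
are computed on the reconstructed component signals rather than the raw
coefficients so that MRA additivity anchors them to the original signal;
for orthogonal wavelets under periodic extension the two agree to
numerical tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .denoise import denoise_epoch
from .preprocess import MultichannelRecording, RegionMap
from .wavelet_bank import WaveletSpec, dyadic_band_map, mra_reconstruct, wavedec, DEFAULT_MODE

__all__ = [
    "UndefinedRelativePowerError",
    "band_powers",
    "relative_power",
    "channel_relative_power",
    "relative_power_table",
    "BAND_ORDER",
]

#: delta..lower_gamma presentation order used in tables.
BAND_ORDER = ("delta", "theta", "alpha", "beta", "lower_gamma")


class UndefinedRelativePowerError(ValueError):
    """All band powers are zero; relative power is undefined."""


def band_powers(
    components: dict[str, np.ndarray], exclude: tuple[str, ...] = ("D1",)
) -> dict[str, float]:
    """Sum-of-squares power of each MRA component, excluding the noise band.

    ``components`` is the {D1..DL, AL} mapping from
    :func:`mwtselect.wavelet_bank.mra_reconstruct`; D1 (higher gamma and
    noise) is excluded by default.
    """
    return {
        label: float(np.sum(np.square(sig)))
        for label, sig in components.items()
        if label not in exclude
    }


def relative_power(powers: dict[str, float]) -> dict[str, float]:
    """Percentage of each component's power in the total (sums to 100)."""
    total = sum(powers.values())
    if total <= 0.0:
        raise UndefinedRelativePowerError("all band powers are zero")
    return {label: 100.0 * p / total for label, p in powers.items()}


def _component_band_names(fs: float, levels: int) -> dict[str, str]:
    bm = dyadic_band_map(fs, levels)
    return {b.label: (b.eeg_band or b.label) for b in bm}


def channel_relative_power(
    signal: np.ndarray,
    w: WaveletSpec,
    fs: float = 256.0,
    levels: int = 5,
    mode: str = DEFAULT_MODE,
) -> dict[str, float]:
    """Relative power of one channel keyed by EEG band name."""
    comps = mra_reconstruct(wavedec(signal, w, levels, mode=mode))
    rp = relative_power(band_powers(comps))
    names = _component_band_names(fs, levels)
    return {names[label]: v for label, v in rp.items()}


def relative_power_table(
    rec: MultichannelRecording,
    w: WaveletSpec,
    region_map: RegionMap | None = None,
    levels: int = 5,
    mode: str = DEFAULT_MODE,
    denoise: bool = True,
    epoch_len: int = 256,
    rule: str = "sure",
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-region relative power table (rows: regions, columns: EEG bands).

    Each channel is optionally denoised epoch-by-epoch with ``w`` first,
    then decomposed over its full length.  By default each channel's RP is
    computed separately and averaged within the region (every row still
    sums to 100%); ``pooled=True`` instead sums the component powers over
    the region's channels before normalising.
    """
    from .denoise import denoise_recording

    if region_map is None:
        from .preprocess import default_region_map

        region_map = default_region_map()
    work = rec
    if denoise:
        work, _ = denoise_recording(rec, w, levels=levels, epoch_len=epoch_len, mode=mode, rule=rule)
    names = _component_band_names(rec.fs, levels)
    per_channel: dict[str, dict[str, float]] = {}
    raw_powers: dict[str, dict[str, float]] = {}
    for ch, label in enumerate(work.labels):
        comps = mra_reconstruct(wavedec(work.data[ch], w, levels, mode=mode))
        powers = band_powers(comps)
        raw_powers[label] = powers
        per_channel[label] = {names[c]: v for c, v in relative_power(powers).items()}

    rows = {}
    for region, chans in region_map.items():
        chans_present = [c for c in chans if c in per_channel]
        if not chans_present:
            continue
        if pooled:
            summed: dict[str, float] = {}
            for c in chans_present:
                for comp, p in raw_powers[c].items():
                    summed[comp] = summed.get(comp, 0.0) + p
            rows[region] = {names[c]: v for c, v in relative_power(summed).items()}
        else:
            rows[region] = {
                band: float(np.mean([per_channel[c][band] for c in chans_present]))
                for band in per_channel[chans_present[0]]
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    ordered = [b for b in BAND_ORDER if b in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    return table[ordered]
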