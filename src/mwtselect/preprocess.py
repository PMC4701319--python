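"""Front-end conditioning of multichannel EEG: line-noise notch, band-pass,
fixed-length epoching and 10-20 scalp-region grouping.

Filter choices: the notch is a second-order IIR notch at the mains frequency
(default 50 Hz, Q = 30); the band-pass is a 4th-order Butterworth with
corners 0.5-64 Hz.  Both are applied forward-backward (zero phase) so that
group delay cannot shift epochs relative to each other and bias the
denoised-vs-raw correlation comparison.  Order of operations is notch first,
then band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "MultichannelRecording",
    "EpochSet",
    "RegionMap",
    "EmptyEpochsError",
    "notch_filter",
    "bandpass_filter",
    "segment_epochs",
    "default_region_map",
    "DEFAULT_NOTCH_HZ",
    "DEFAULT_BAND_HZ",
    "EPOCH_LEN_DEFAULT",
]

DEFAULT_NOTCH_HZ = 50.0
DEFAULT_NOTCH_Q = 30.0
DEFAULT_BAND_HZ = (0.5, 64.0)
EPOCH_LEN_DEFAULT = 256  # samples (1 s at 256 Hz)


class EmptyEpochsError(ValueError):
    """Requested epoch length exceeds the recording length."""


@dataclass
class MultichannelRecording:
    """EEG recording: channels x samples matrix in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(lb.lower() for lb in self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "MultichannelRecording":
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length segments, channels x epochs x samples."""

    epochs: np.ndarray
    fs: float
    epoch_len: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs array must be channels x epochs x samples")
        if self.epochs.shape[2] != self.epoch_len:
            raise ValueError("last axis must equal epoch_len")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.epochs.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]


@dataclass(frozen=True)
class RegionMap:
    """Mapping from scalp region name to 10-20 channel labels."""

    regions: dict[str, tuple[str, ...]]

    def __iter__(self):
        return iter(self.regions)

    def items(self):
        return self.regions.items()

    def __getitem__(self, region: str) -> tuple[str, ...]:
        return self.regions[region]

    def region_of(self, label: str) -> str:
        low = label.lower()
        for region, chans in self.regions.items():
            if low in (c.lower() for c in chans):
                return region
        raise KeyError(f"channel {label!r} not in any region")

    def all_channels(self) -> set[str]:
        return {c for chans in self.regions.values() for c in chans}


def default_region_map() -> RegionMap:
    """The five scalp regions of the 19-channel 10-20 montage."""
    return RegionMap(
        regions={
            "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
            "temporal": ("T3", "T4", "T5", "T6"),
            "parietal": ("P3", "P4", "Pz"),
            "occipital": ("O1", "O2"),
            "central": ("C3", "C4", "Cz"),
        }
    )


def notch_filter(
    rec: MultichannelRecording,
    f0: float = DEFAULT_NOTCH_HZ,
    q: float = DEFAULT_NOTCH_Q,
) -> MultichannelRecording:
    """Zero-phase second-order IIR notch at the mains frequency."""
    if not 0 < f0 < rec.fs / 2:
        raise ValueError(
            f"notch frequency {f0} Hz must lie in (0, Nyquist={rec.fs / 2})"
        )
    b, a = sps.iirnotch(f0, q, fs=rec.fs)
    return rec.copy_with(sps.filtfilt(b, a, rec.data, axis=-1))


def bandpass_filter(
    rec: MultichannelRecording,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
    order: int = 4,
) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass (default 0.5-64 Hz, order 4)."""
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"band corners must satisfy 0 < {low} < {high} < Nyquist={rec.fs / 2}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(sps.sosfiltfilt(sos, rec.data, axis=-1))


def segment_epochs(rec: MultichannelRecording, epoch_len: int = EPOCH_LEN_DEFAULT) -> EpochSet:
    """Cut each channel into non-overlapping epochs of ``epoch_len`` samples.

    The trailing remainder (if the length does not divide exactly) is
    discarded with a warning.
    """
    if epoch_len < 1:
        raise ValueError("epoch_len must be >= 1")
    n = rec.n_samples
    n_epochs = n // epoch_len
    if n_epochs == 0:
        raise EmptyEpochsError(
            f"epoch length {epoch_len} exceeds recording length {n}"
        )
    remainder = n - n_epochs * epoch_len
    if remainder:
        warnings.warn(
            f"discarding {remainder} trailing samples that do not fill an epoch",
            stacklevel=2,
        )
    cut = rec.data[:, : n_epochs * epoch_len]
    epochs = cut.reshape(rec.n_channels, n_epochs, epoch_len)
    return EpochSet(epochs=epochs, fs=rec.fs, epoch_len=epoch_len, labels=list(rec.labels))
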