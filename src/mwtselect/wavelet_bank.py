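"""Orthogonal mother-wavelet candidate bank and dyadic filter-bank machinery.

The candidate bank is the 45 orthogonal wavelets conventionally used for
biosignal work: Daubechies db1-db20, Symlets sym1-sym20 and Coiflets
coif1-coif5.  Symlets conventionally start at sym2; ``sym1`` is provided as
an alias of the Haar wavelet (identical to ``db1``) so that the bank has
exactly 45 members with the conventional names.

Each wavelet is represented by its quadrature-mirror filter pair: the
low-pass (scaling) analysis filter h and the high-pass (wavelet) analysis
filter g, with g[n] = (-1)^n h[L-1-n].  Decomposition is the standard Mallat
cascade: convolve with h and g and downsample by two at each level, yielding
approximation coefficients cA_L and detail coefficients cD_1..cD_L whose
dyadic frequency bands halve per level.

Boundary handling is selectable: ``"symmetric"`` (half-point mirror
extension, the default — avoids wrap-around transients on real epochs) or
``"periodization"`` (circular extension, which makes the transform exactly
orthonormal on even-length inputs so coefficient energy equals signal
energy).  Filter coefficients are taken from PyWavelets and validated
against the orthonormality invariants at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "BandMap",
    "BandInterval",
    "InvalidFilterError",
    "DecompositionDepthError",
    "ReconstructionError",
    "list_candidate_wavelets",
    "get_wavelet",
    "qmf_highpass",
    "dwt_level",
    "idwt_level",
    "wavedec",
    "waverec",
    "mra_reconstruct",
    "dyadic_band_map",
    "CANDIDATE_NAMES",
]

DEFAULT_MODE = "symmetric"

#: Conventional EEG band names for the dyadic edges at fs = 256 Hz, 5 levels.
_EEG_BAND_NAMES = {
    (0.0, 4.0): "delta",
    (4.0, 8.0): "theta",
    (8.0, 16.0): "alpha",
    (16.0, 32.0): "beta",
    (32.0, 64.0): "lower_gamma",
    (64.0, 128.0): "higher_gamma_noise",
}

CANDIDATE_NAMES: tuple[str, ...] = tuple(
    [f"db{i}" for i in range(1, 21)]
    + [f"sym{i}" for i in range(1, 21)]
    + [f"coif{i}" for i in range(1, 6)]
)


class InvalidFilterError(ValueError):
    """A filter vector violates the orthogonal scaling-filter invariants."""


class DecompositionDepthError(ValueError):
    """The signal is too short for the requested decomposition depth."""


class ReconstructionError(ValueError):
    """Coefficient vectors are mutually inconsistent for reconstruction."""


@dataclass(frozen=True)
class WaveletSpec:
    """One orthogonal wavelet candidate, identified with its QMF filter pair.

    ``dec_lo`` (h) is the scaling/low-pass analysis filter; ``dec_hi`` (g) is
    the wavelet/high-pass analysis filter; ``rec_lo``/``rec_hi`` are the
    matching synthesis pair.  The scaling function phi and wavelet psi are
    represented implicitly by these filters.
    """

    name: str
    family: str  # "daubechies" | "symlet" | "coiflet"
    order: int
    dec_lo: np.ndarray = field(repr=False)
    dec_hi: np.ndarray = field(repr=False)
    rec_lo: np.ndarray = field(repr=False)
    rec_hi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            object.__setattr__(
                self, attr, np.asarray(getattr(self, attr), dtype=float)
            )
        self.validate()

    @property
    def filter_length(self) -> int:
        return self.dec_lo.size

    def validate(self, tol: float = 1e-10) -> None:
        """Check the orthonormal scaling-filter invariants."""
        h, g = self.dec_lo, self.dec_hi
        if h.size == 0 or h.size % 2 or h.size != g.size:
            raise InvalidFilterError(
                f"{self.name}: analysis filters must have equal even length"
            )
        if abs(h.sum() - np.sqrt(2.0)) > tol:
            raise InvalidFilterError(f"{self.name}: sum(dec_lo) != sqrt(2)")
        if abs(g.sum()) > tol:
            raise InvalidFilterError(f"{self.name}: sum(dec_hi) != 0")
        if abs(h @ h - 1.0) > tol:
            raise InvalidFilterError(f"{self.name}: dec_lo not unit norm")
        for lag in range(2, h.size, 2):
            if abs(h[lag:] @ h[:-lag]) > tol:
                raise InvalidFilterError(
                    f"{self.name}: dec_lo not orthogonal to its even shifts"
                )

    def to_pywt(self) -> pywt.Wavelet:
        return _pywt_wavelet(self.name)


@dataclass
class WaveletDecomposition:
    """Coefficients of a dyadic decomposition of one epoch.

    ``details[0]`` is the finest level cD_1 (highest frequency band);
    ``details[levels-1]`` is cD_L.  ``approx`` is cA_L.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    levels: int
    wavelet: WaveletSpec
    original_length: int
    mode: str = DEFAULT_MODE

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ReconstructionError(
                f"expected {self.levels} detail vectors, got {len(self.details)}"
            )

    def coefficient_energy(self) -> float:
        """Total squared coefficient magnitude over all sets."""
        return float(
            self.approx @ self.approx
            + sum(d @ d for d in self.details)
        )

    def component_labels(self) -> list[str]:
        return [f"D{k}" for k in range(1, self.levels + 1)] + [f"A{self.levels}"]


@dataclass(frozen=True)
class BandInterval:
    label: str  # "D1".."DL" or "AL"
    low_hz: float
    high_hz: float
    eeg_band: str | None  # canonical name where edges match, else None


@dataclass(frozen=True)
class BandMap:
    """Dyadic tiling of [0, fs/2] by the decomposition components."""

    bands: tuple[BandInterval, ...]
    fs: float
    levels: int

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, label: str) -> BandInterval:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    def validate(self, tol: float = 1e-9) -> None:
        edges = sorted(self.bands, key=lambda b: b.low_hz)
        if abs(edges[0].low_hz) > tol or abs(edges[-1].high_hz - self.fs / 2) > tol:
            raise ValueError("bands do not span [0, fs/2]")
        for a, b in zip(edges, edges[1:]):
            if abs(a.high_hz - b.low_hz) > tol:
                raise ValueError("bands do not tile contiguously")


@lru_cache(maxsize=64)
def _pywt_wavelet(name: str) -> pywt.Wavelet:
    if name == "sym1":  # alias: Symlet order 1 is the Haar wavelet
        w = pywt.Wavelet("db1")
        return pywt.Wavelet("sym1", filter_bank=w.filter_bank)
    return pywt.Wavelet(name)


@lru_cache(maxsize=64)
def get_wavelet(name: str) -> WaveletSpec:
    """Build the validated :class:`WaveletSpec` for a conventional name."""
    if name not in CANDIDATE_NAMES:
        raise KeyError(f"unknown candidate wavelet {name!r}")
    w = _pywt_wavelet(name)
    if name.startswith("db"):
        family, order = "daubechies", int(name[2:])
    elif name.startswith("sym"):
        family, order = "symlet", int(name[3:])
    else:
        family, order = "coiflet", int(name[4:])
    return WaveletSpec(
        name=name,
        family=family,
        order=order,
        dec_lo=np.asarray(w.dec_lo),
        dec_hi=np.asarray(w.dec_hi),
        rec_lo=np.asarray(w.rec_lo),
        rec_hi=np.asarray(w.rec_hi),
    )


def list_candidate_wavelets() -> list[WaveletSpec]:
    """The 45-member candidate bank, ordered db1..db20, sym1..sym20, coif1..coif5."""
    return [get_wavelet(name) for name in CANDIDATE_NAMES]


def qmf_highpass(dec_lo: Sequence[float]) -> np.ndarray:
    """High-pass quadrature-mirror filter from the scaling filter.

    Convention: ``g[n] = (-1)**n * h[L-1-n]`` (alternating signs applied to
    the time-reversed filter).  For Haar this yields
    ``[1/sqrt(2), -1/sqrt(2)]``.  Guaranteed orthogonal to ``dec_lo``.
    """
    h = np.asarray(dec_lo, dtype=float)
    if h.size == 0 or h.size % 2:
        raise InvalidFilterError("scaling filter must have even, nonzero length")
    signs = np.where(np.arange(h.size) % 2 == 0, 1.0, -1.0)
    return signs * h[::-1]


def _check_mode(mode: str) -> str:
    if mode not in ("symmetric", "periodization"):
        raise ValueError(f"unsupported extension mode {mode!r}")
    return mode


def dwt_level(
    signal: Sequence[float], w: WaveletSpec, mode: str = DEFAULT_MODE
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: convolve with (h, g) and downsample by two.

    With ``mode="periodization"`` on even-length input the step is exactly
    orthonormal, so the coefficient energy equals the signal energy.
    """
    x = np.asarray(signal, dtype=float)
    _check_mode(mode)
    if x.size < w.filter_length:
        raise DecompositionDepthError(
            f"signal length {x.size} shorter than {w.name} filter "
            f"({w.filter_length} taps)"
        )
    cA, cD = pywt.dwt(x, w.to_pywt(), mode=mode)
    return cA, cD


def idwt_level(
    approx: Sequence[float],
    detail: Sequence[float],
    w: WaveletSpec,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """Exact left-inverse of :func:`dwt_level` under the same extension mode."""
    cA = np.asarray(approx, dtype=float)
    cD = np.asarray(detail, dtype=float)
    _check_mode(mode)
    if cA.size != cD.size:
        raise ReconstructionError(
            f"approx length {cA.size} != detail length {cD.size}"
        )
    return pywt.idwt(cA, cD, w.to_pywt(), mode=mode)


def wavedec(
    signal: Sequence[float],
    w: WaveletSpec,
    levels: int,
    mode: str = DEFAULT_MODE,
) -> WaveletDecomposition:
    """Iterated dyadic decomposition into cD_1..cD_L and cA_L."""
    x = np.asarray(signal, dtype=float)
    _check_mode(mode)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    # depth rule: first level must cover the filter, and every level needs at
    # least two samples to split (boundary extension supplies the overlap for
    # long filters at coarse levels)
    if x.size < w.filter_length:
        raise DecompositionDepthError(
            f"signal length {x.size} shorter than {w.name} filter "
            f"({w.filter_length} taps)"
        )
    if x.size < 2**levels:
        raise DecompositionDepthError(
            f"{levels}-level decomposition too deep for length {x.size}"
        )
    with warnings.catch_warnings():
        # pywt warns when levels exceed its boundary-effect-free maximum;
        # long-filter wavelets on 256-sample epochs rely on extension there
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, w.to_pywt(), mode=mode, level=levels)
    approx = coeffs[0]
    details_coarse_to_fine = coeffs[1:]  # cD_L .. cD_1
    details = list(details_coarse_to_fine[::-1])  # cD_1 .. cD_L
    return WaveletDecomposition(
        approx=approx,
        details=details,
        levels=levels,
        wavelet=w,
        original_length=x.size,
        mode=mode,
    )


def _to_pywt_coeffs(d: WaveletDecomposition) -> list[np.ndarray]:
    return [d.approx] + list(d.details[::-1])


def waverec(d: WaveletDecomposition) -> np.ndarray:
    """Inverse of :func:`wavedec`; output trimmed to the original length."""
    y = pywt.waverec(_to_pywt_coeffs(d), d.wavelet.to_pywt(), mode=d.mode)
    return y[: d.original_length]


def mra_reconstruct(d: WaveletDecomposition) -> dict[str, np.ndarray]:
    """Per-component reconstructions {D1..DL, AL} that sum to the signal.

    Each component is the reconstruction of the decomposition with every
    other coefficient set zeroed; by linearity of the synthesis bank the
    components add up to ``waverec(d)``.
    """
    out: dict[str, np.ndarray] = {}
    zero_sets = [np.zeros_like(c) for c in _to_pywt_coeffs(d)]
    for idx, label in enumerate([f"A{d.levels}"] + [f"D{k}" for k in range(d.levels, 0, -1)]):
        coeffs = list(zero_sets)
        coeffs[idx] = _to_pywt_coeffs(d)[idx]
        y = pywt.waverec(coeffs, d.wavelet.to_pywt(), mode=d.mode)
        out[label] = y[: d.original_length]
    # return in D1..DL, AL order
    ordered = {f"D{k}": out[f"D{k}"] for k in range(1, d.levels + 1)}
    ordered[f"A{d.levels}"] = out[f"A{d.levels}"]
    return ordered


def dyadic_band_map(fs: float, levels: int) -> BandMap:
    """Frequency bands of the decomposition components.

    Detail level k occupies [fs/2^(k+1), fs/2^k]; the approximation occupies
    [0, fs/2^(L+1)].  At fs = 256 Hz with 5 levels this is the conventional
    EEG table: D1 64-128 Hz (higher gamma and noise), D2 32-64 (lower gamma),
    D3 16-32 (beta), D4 8-16 (alpha), D5 4-8 (theta), A5 0-4 (delta).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    bands = []
    for k in range(1, levels + 1):
        low, high = fs / 2 ** (k + 1), fs / 2**k
        bands.append(
            BandInterval(f"D{k}", low, high, _EEG_BAND_NAMES.get((low, high)))
        )
    low_a = 0.0
    high_a = fs / 2 ** (levels + 1)
    bands.append(
        BandInterval(f"A{levels}", low_a, high_a, _EEG_BAND_NAMES.get((low_a, high_a)))
    )
    bm = BandMap(bands=tuple(bands), fs=float(fs), levels=levels)
    bm.validate()
    return bm
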