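"""Enumerate the 45-wavelet candidate bank and its dyadic EEG band map.

Prints the bank (Daubechies db1-db20, Symlets sym1-sym20, Coiflets
coif1-coif5) and the frequency bands a 5-level decomposition assigns at a
256 Hz sampling rate: each detail level halves the band, so D4 covers the
alpha range 8-16 Hz and the final approximation A5 covers delta 0-4 Hz.
"""

from mwtselect import dyadic_band_map, list_candidate_wavelets

bank = list_candidate_wavelets()
print(f"candidate bank: {len(bank)} wavelets")
print("  " + ", ".join(w.name for w in bank))

print("\nfilter lengths (taps): db/sym use 2*order, coif uses 6*order")
for name in ("db1", "db20", "sym9", "coif5"):
    w = next(w for w in bank if w.name == name)
    print(f"  {w.name:>6s}: {w.filter_length} taps")

print("\ndyadic band map at fs = 256 Hz, 5 levels:")
for band in dyadic_band_map(256.0, 5):
    eeg = band.eeg_band or "-"
    print(f"  {band.label}: {band.low_hz:6.1f} - {band.high_hz:6.1f} Hz  ({eeg})")
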