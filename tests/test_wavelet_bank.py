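"""Candidate bank, QMF relation, transforms and the dyadic band map."""

import numpy as np
import pytest
from scipy.signal import periodogram

from mwtselect.wavelet_bank import (
    CANDIDATE_NAMES,
    DecompositionDepthError,
    InvalidFilterError,
    ReconstructionError,
    dwt_level,
    dyadic_band_map,
    get_wavelet,
    idwt_level,
    list_candidate_wavelets,
    mra_reconstruct,
    qmf_highpass,
    wavedec,
    waverec,
)

SQRT2 = np.sqrt(2.0)


class TestCandidateBank:
    def test_bank_has_45_members_in_conventional_order(self):
        bank = list_candidate_wavelets()
        assert len(bank) == 45
        assert [w.name for w in bank] == list(CANDIDATE_NAMES)
        assert CANDIDATE_NAMES[0] == "db1"
        assert CANDIDATE_NAMES[19] == "db20"
        assert CANDIDATE_NAMES[20] == "sym1"
        assert CANDIDATE_NAMES[-1] == "coif5"

    @pytest.mark.parametrize("name", CANDIDATE_NAMES)
    def test_filter_invariants(self, name):
        w = get_wavelet(name)
        h, g = w.dec_lo, w.dec_hi
        assert h.size == g.size and h.size % 2 == 0
        assert abs(h.sum() - SQRT2) < 1e-10
        assert abs(g.sum()) < 1e-10
        assert abs(h @ h - 1.0) < 1e-10
        for lag in range(2, h.size, 2):
            assert abs(h[lag:] @ h[:-lag]) < 1e-10

    def test_haar_scaling_filter(self, haar):
        np.testing.assert_allclose(haar.dec_lo, [1 / SQRT2, 1 / SQRT2])

    def test_filter_lengths_follow_family_rules(self):
        # 2*order taps for db/sym, 6*order for coif
        assert get_wavelet("coif1").filter_length == 6
        assert get_wavelet("db20").filter_length == 40
        assert get_wavelet("sym9").filter_length == 18
        assert get_wavelet("coif5").filter_length == 30

    def test_sym1_aliases_haar(self, haar):
        s1 = get_wavelet("sym1")
        np.testing.assert_array_equal(s1.dec_lo, haar.dec_lo)
        np.testing.assert_array_equal(s1.dec_hi, haar.dec_hi)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            get_wavelet("morl")


class TestQmf:
    def test_haar_pair(self, haar):
        np.testing.assert_allclose(
            qmf_highpass(haar.dec_lo), [1 / SQRT2, -1 / SQRT2]
        )

    @pytest.mark.parametrize("name", ["db1", "db4", "sym9", "coif3"])
    def test_qmf_orthogonal_unit_norm_zero_sum(self, name):
        h = get_wavelet(name).dec_lo
        g = qmf_highpass(h)
        assert abs(g @ h) < 1e-10
        assert abs(g @ g - 1.0) < 1e-10
        assert abs(g.sum()) < 1e-10

    def test_odd_or_empty_filter_rejected(self):
        with pytest.raises(InvalidFilterError):
            qmf_highpass([0.5, 0.5, 0.5])
        with pytest.raises(InvalidFilterError):
            qmf_highpass([])


class TestSingleLevel:
    def test_haar_constant_signal(self, haar):
        cA, cD = dwt_level([1.0, 1.0, 1.0, 1.0], haar, mode="periodization")
        np.testing.assert_allclose(cA, [SQRT2, SQRT2])
        np.testing.assert_allclose(cD, [0.0, 0.0], atol=1e-12)

    def test_haar_alternating_signal(self, haar):
        cA, cD = dwt_level([1.0, -1.0, 1.0, -1.0], haar, mode="periodization")
        np.testing.assert_allclose(cA, [0.0, 0.0], atol=1e-12)
        assert abs(cD @ cD - 4.0) < 1e-10

    def test_haar_inverse_of_constant(self, haar):
        y = idwt_level([SQRT2, SQRT2], [0.0, 0.0], haar, mode="periodization")
        np.testing.assert_allclose(y, [1.0, 1.0, 1.0, 1.0])

    def test_zero_coefficients_reconstruct_zero(self, db4):
        y = idwt_level(np.zeros(8), np.zeros(8), db4)
        np.testing.assert_allclose(y, 0.0, atol=1e-14)

    @pytest.mark.parametrize("mode", ["symmetric", "periodization"])
    def test_round_trip_db7(self, rng, mode):
        w = get_wavelet("db7")
        x = rng.standard_normal(256)
        cA, cD = dwt_level(x, w, mode=mode)
        y = idwt_level(cA, cD, w, mode=mode)
        np.testing.assert_allclose(y[: x.size], x, atol=1e-10)

    def test_coefficient_round_trip(self, rng, db4):
        # dwt(idwt(a, d)) = (a, d) under periodization
        a = rng.standard_normal(16)
        d = rng.standard_normal(16)
        y = idwt_level(a, d, db4, mode="periodization")
        a2, d2 = dwt_level(y, db4, mode="periodization")
        np.testing.assert_allclose(a2, a, atol=1e-10)
        np.testing.assert_allclose(d2, d, atol=1e-10)

    def test_energy_conserved_periodization(self, rng):
        w = get_wavelet("sym9")
        x = rng.standard_normal(256)
        cA, cD = dwt_level(x, w, mode="periodization")
        assert abs((cA @ cA + cD @ cD) - x @ x) / (x @ x) < 1e-10

    def test_signal_shorter_than_filter_rejected(self):
        with pytest.raises(DecompositionDepthError):
            dwt_level(np.ones(4), get_wavelet("db20"))

    def test_length_mismatch_rejected(self, db4):
        with pytest.raises(ReconstructionError):
            idwt_level(np.zeros(8), np.zeros(7), db4)


class TestMultiLevel:
    def test_five_levels_give_six_coefficient_sets(self, rng):
        for name in ("db1", "sym9", "coif5", "db20"):
            d = wavedec(rng.standard_normal(256), get_wavelet(name), 5)
            assert d.levels == 5
            assert len(d.details) == 5
            assert d.component_labels() == ["D1", "D2", "D3", "D4", "D5", "A5"]

    @pytest.mark.parametrize("name", ["db3", "sym5", "coif2"])
    def test_constant_signal_has_no_detail(self, name):
        d = wavedec(np.full(256, 3.7), get_wavelet(name), 5, mode="periodization")
        for det in d.details:
            assert np.max(np.abs(det)) < 1e-10

    @pytest.mark.parametrize("mode", ["symmetric", "periodization"])
    def test_round_trip(self, rng, mode, sym9):
        x = rng.standard_normal(256)
        np.testing.assert_allclose(
            waverec(wavedec(x, sym9, 5, mode=mode)), x, atol=1e-10
        )

    def test_db1_sym1_identical_decompositions(self, rng):
        x = rng.standard_normal(256)
        d1 = wavedec(x, get_wavelet("db1"), 5)
        s1 = wavedec(x, get_wavelet("sym1"), 5)
        np.testing.assert_array_equal(d1.approx, s1.approx)
        for a, b in zip(d1.details, s1.details):
            np.testing.assert_array_equal(a, b)

    def test_excessive_depth_rejected(self, haar):
        with pytest.raises(DecompositionDepthError):
            wavedec(np.ones(16), haar, 5)


class TestMra:
    def test_components_sum_to_signal(self, rng, sym9):
        x = rng.standard_normal(256)
        comps = mra_reconstruct(wavedec(x, sym9, 5))
        assert set(comps) == {"D1", "D2", "D3", "D4", "D5", "A5"}
        np.testing.assert_allclose(sum(comps.values()), x, atol=1e-8)

    def test_dc_signal_lands_in_approximation(self, db4):
        comps = mra_reconstruct(wavedec(np.full(256, 5.0), db4, 5, mode="periodization"))
        energies = {k: float(v @ v) for k, v in comps.items()}
        assert max(energies, key=energies.get) == "A5"
        assert energies["A5"] > 0.999 * sum(energies.values())

    def test_48hz_sinusoid_lands_in_d2(self, db4):
        # independent band oracle: 48 Hz lies in the 32-64 Hz band; confirm
        # with a periodogram that the D2 component carries the peak
        fs = 256.0
        t = np.arange(256) / fs
        x = np.sin(2 * np.pi * 48.0 * t)
        comps = mra_reconstruct(wavedec(x, db4, 5, mode="periodization"))
        energies = {k: float(v @ v) for k, v in comps.items()}
        assert max(energies, key=energies.get) == "D2"
        f, p = periodogram(comps["D2"], fs=fs)
        assert 32.0 <= f[np.argmax(p)] <= 64.0


class TestBandMap:
    def test_conventional_eeg_table(self):
        bm = dyadic_band_map(256.0, 5)
        expected = {
            "D1": (64.0, 128.0, "higher_gamma_noise"),
            "D2": (32.0, 64.0, "lower_gamma"),
            "D3": (16.0, 32.0, "beta"),
            "D4": (8.0, 16.0, "alpha"),
            "D5": (4.0, 8.0, "theta"),
            "A5": (0.0, 4.0, "delta"),
        }
        for label, (lo, hi, band) in expected.items():
            b = bm[label]
            assert (b.low_hz, b.high_hz, b.eeg_band) == (lo, hi, band)

    def test_single_split(self):
        bm = dyadic_band_map(2.0, 1)
        assert (bm["D1"].low_hz, bm["D1"].high_hz) == (0.5, 1.0)
        assert (bm["A1"].low_hz, bm["A1"].high_hz) == (0.0, 0.5)

    def test_bands_tile_nyquist_range(self):
        bm = dyadic_band_map(256.0, 5)
        intervals = sorted((b.low_hz, b.high_hz) for b in bm)
        assert intervals[0][0] == 0.0
        assert intervals[-1][1] == 128.0
        for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
            assert hi == lo  # contiguous, disjoint interiors

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dyadic_band_map(-1.0, 5)
        with pytest.raises(ValueError):
            dyadic_band_map(256.0, 0)
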