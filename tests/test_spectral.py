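"""Analytic signals, Hilbert spectra and spectral features."""

import numpy as np
import pytest

from emghht.decomposition import EEMDConfig, IMFSet, eemd_decompose
from emghht.preprocess import StanceSegment
from emghht.spectral import (
    HIGH_BAND,
    LOW_BAND,
    UndefinedFeaturesError,
    analysis_windows,
    analytic_signal,
    band_power,
    hilbert_spectrum,
    locate_max_energy,
    marginal_spectrum,
    normalize_band_power,
)

from conftest import FS, tone


def single_imf_spectrum(x, fs=FS, **kw):
    return hilbert_spectrum(IMFSet(imfs=x[None, :], residual=np.zeros(len(x))), fs, **kw)


class TestAnalyticSignal:
    def test_pure_tone_amplitude_and_frequency(self):
        a = analytic_signal(np.cos(2 * np.pi * 50 * np.arange(1000) / FS), FS)
        assert np.allclose(a.amplitude[100:-100], 1.0, rtol=0.01)
        assert np.all(np.abs(a.inst_freq[100:-100] - 50.0) < 0.5)

    def test_am_tone_tracks_modulator(self):
        t = np.arange(1000) / FS
        modulator = 1 + 0.5 * np.sin(2 * np.pi * 2 * t)
        a = analytic_signal(modulator * np.cos(2 * np.pi * 100 * t), FS)
        assert np.allclose(a.amplitude[100:-100], modulator[100:-100], rtol=0.03)

    def test_zero_signal_convention(self):
        a = analytic_signal(np.zeros(100), FS)
        assert np.allclose(a.amplitude, 0.0)
        assert np.allclose(a.inst_freq, 0.0)
        assert np.all(np.isfinite(a.inst_freq))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.ones(4), FS)


class TestHilbertSpectrum:
    def test_tone_energy_concentrates_at_its_frequency(self):
        hs = single_imf_spectrum(tone(50.0))
        h = marginal_spectrum(hs)
        near = (hs.bin_centers >= 48.0) & (hs.bin_centers <= 52.0)
        assert h[near].sum() >= 0.95 * h.sum()

    def test_energy_conservation_identity(self):
        x = tone(40.0) + 0.5 * tone(120.0)
        imfset = eemd_decompose(x, EEMDConfig(ensemble_size=10, seed=0))
        hs = hilbert_spectrum(imfset, FS)
        expected = 0.0
        for imf in imfset.imfs:
            a = analytic_signal(imf, FS)
            ok = (a.inst_freq > 0) & (a.inst_freq <= 500.0)
            expected += np.sum(a.amplitude[ok] ** 2)
        assert np.isclose(hs.energy.sum(), expected, rtol=1e-12)

    def test_empty_imf_list_gives_zero_matrix(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 200)), residual=np.zeros(200)), FS)
        assert hs.energy.shape == (500, 200)
        assert np.all(hs.energy == 0)

    def test_residual_excluded(self):
        imfset = IMFSet(imfs=np.zeros((0, 300)), residual=np.linspace(0, 5, 300))
        assert hilbert_spectrum(imfset, FS).energy.sum() == 0.0


class TestMarginalSpectrum:
    def test_two_tone_peaks(self, two_tone):
        mix, _, _ = two_tone
        imfset = eemd_decompose(mix, EEMDConfig(ensemble_size=10, seed=3))
        hs = hilbert_spectrum(imfset, FS)
        h = marginal_spectrum(hs)
        # dominant energy near each tone
        for f0 in (25.0, 150.0):
            near = (hs.bin_centers >= f0 - 3) & (hs.bin_centers <= f0 + 3)
            far = (hs.bin_centers >= f0 + 20) & (hs.bin_centers <= f0 + 40)
            assert h[near].sum() > h[far].sum()

    def test_total_preserved(self):
        hs = single_imf_spectrum(tone(60.0))
        assert np.isclose(marginal_spectrum(hs).sum(), hs.energy.sum(), rtol=1e-12)

    def test_all_zero(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 50)), residual=np.zeros(50)), FS)
        assert np.all(marginal_spectrum(hs) == 0)


class TestLocateMaxEnergy:
    def _burst_spectrum(self, center_frac=0.30, freq=120.0, n=600, onset=100, offset=500):
        t = np.arange(n) / FS
        u = (np.arange(n) - onset) / (offset - onset)
        env = np.exp(-0.5 * ((u - center_frac) / 0.08) ** 2)
        x = env * np.cos(2 * np.pi * freq * t)
        return single_imf_spectrum(x), StanceSegment(onset, offset, 100)

    def test_burst_timing_and_frequency_recovered(self):
        hs, seg = self._burst_spectrum()
        sf = locate_max_energy(hs, seg)
        assert abs(sf.s_max_pct - 30.0) <= 2.0
        assert abs(sf.f_max_hz - 120.0) <= 5.0

    def test_uniform_energy_tie_breaks_to_origin(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 300)), residual=np.zeros(300)), FS)
        energy = np.ones_like(hs.energy)
        hs = type(hs)(energy=energy, freq_edges=hs.freq_edges, fs=hs.fs)
        sf = locate_max_energy(hs, StanceSegment(50, 250, 50))
        assert sf.s_max_pct == 0.0
        assert sf.f_max_hz == hs.bin_centers[0]

    def test_equal_bursts_earliest_wins(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 500)), residual=np.zeros(500)), FS)
        energy = np.zeros_like(hs.energy)
        seg = StanceSegment(100, 400, 100)
        for frac in (0.20, 0.60):
            energy[80, 100 + int(frac * 300)] = 1.0
        hs = type(hs)(energy=energy, freq_edges=hs.freq_edges, fs=hs.fs)
        sf = locate_max_energy(hs, seg)
        assert abs(sf.s_max_pct - 20.0) <= 2.0

    def test_silent_stance_raises(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 300)), residual=np.zeros(300)), FS)
        with pytest.raises(UndefinedFeaturesError):
            locate_max_energy(hs, StanceSegment(50, 250, 50))

    @pytest.mark.parametrize("freq", [20.0, 60.0, 120.0, 200.0])
    def test_tone_frequency_recovery(self, freq):
        hs, seg = self._burst_spectrum(freq=freq)
        sf = locate_max_energy(hs, seg)
        assert abs(sf.f_max_hz - freq) <= max(2.0, 0.03 * freq)


class TestBandPower:
    def test_low_tone_energy_in_low_band(self):
        hs = single_imf_spectrum(tone(30.0))
        total = hs.energy.sum()
        assert band_power(hs, LOW_BAND, (0, 1000)) >= 0.95 * total
        assert band_power(hs, HIGH_BAND, (0, 1000)) <= 0.05 * total

    def test_partition_bound(self, two_tone):
        mix, _, _ = two_tone
        imfset = eemd_decompose(mix, EEMDConfig(ensemble_size=10, seed=7))
        hs = hilbert_spectrum(imfset, FS)
        w = (200, 800)
        low = band_power(hs, LOW_BAND, w)
        high = band_power(hs, HIGH_BAND, w)
        assert low + high <= hs.energy[:, w[0] : w[1]].sum() + 1e-9

    def test_zero_energy_window(self):
        hs = hilbert_spectrum(IMFSet(imfs=np.zeros((0, 300)), residual=np.zeros(300)), FS)
        assert band_power(hs, LOW_BAND, (0, 300)) == 0.0

    def test_empty_window_rejected(self):
        hs = single_imf_spectrum(tone(30.0))
        with pytest.raises(ValueError, match="empty"):
            band_power(hs, LOW_BAND, (500, 500))


class TestAnalysisWindows:
    def test_study_windows(self):
        seg = StanceSegment(200, 449, 100)  # 250-sample stance
        w = analysis_windows(seg, FS)
        assert w["pre"] == (100, 200)
        assert w["early"] == (200, 250)
        assert w["mid"] == (250, 300)


class TestNormalizeBandPower:
    def test_max_normalization(self):
        assert np.allclose(normalize_band_power([2.0, 4.0, 8.0]), [25.0, 50.0, 100.0])

    def test_singleton(self):
        assert np.allclose(normalize_band_power([3.7]), [100.0])

    def test_scale_invariance(self):
        raw = np.array([1.0, 2.5, 4.0])
        assert np.allclose(normalize_band_power(raw), normalize_band_power(17.3 * raw))

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            out = normalize_band_power([0.0, 0.0])
        assert np.all(out == 0)
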