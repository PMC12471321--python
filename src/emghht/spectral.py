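"""Hilbert-Huang spectral analysis of IMF sets.

Each IMF is turned into an analytic signal z(t) = S(t) + i y(t) via the
Hilbert transform; its modulus a(t) is the instantaneous amplitude and
the derivative of its unwrapped phase gives the instantaneous frequency
f(t).  Depositing a_i^2(t) at (f_i(t), t) for every IMF builds the
Hilbert spectrum H(f, t); summing over time yields the marginal Hilbert
spectrum h(f).  From the stance-restricted spectrum we read off the
timing (S_max, % of stance) and frequency (F_max, Hz) of maximum
energy, and band powers in the low (0-60 Hz] and high (60-200 Hz]
bands over the pre-contact (100 ms), 0-20% and 20-40% stance windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .decomposition import IMFSet
from .preprocess import StanceSegment

__all__ = [
    "AnalyticSignal",
    "HilbertSpectrum",
    "SpectralFeatures",
    "UndefinedFeaturesError",
    "analytic_signal",
    "hilbert_spectrum",
    "marginal_spectrum",
    "locate_max_energy",
    "band_power",
    "analysis_windows",
    "normalize_band_power",
    "LOW_BAND",
    "HIGH_BAND",
]

#: Analysis bands, half-open (low, high] in Hz.
LOW_BAND = (0.0, 60.0)
HIGH_BAND = (60.0, 200.0)

#: Amplitudes below this are treated as silence: the instantaneous
#: frequency is set to 0 there rather than left numerically undefined.
_AMP_EPS = 1e-12


class UndefinedFeaturesError(ValueError):
    """Raised when the stance region carries no spectral energy."""


@dataclass(frozen=True)
class AnalyticSignal:
    """Instantaneous amplitude, unwrapped phase and frequency of one IMF."""

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray
    fs: float


@dataclass(frozen=True)
class HilbertSpectrum:
    """Energy (amplitude squared) binned on the frequency-time plane.

    ``energy[i, t]`` is the energy deposited in frequency bin i (the
    half-open interval ``(freq_edges[i], freq_edges[i+1]]``) at time
    sample t.
    """

    energy: np.ndarray  # (n_bins, n_samples)
    freq_edges: np.ndarray  # (n_bins + 1,)
    fs: float
    t0: float = 0.0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.freq_edges[1] - self.freq_edges[0])


@dataclass(frozen=True)
class SpectralFeatures:
    """Scalar Hilbert-spectral features of one muscle in one trial."""

    s_max_pct: float  # stance-phase timing of maximum energy, % of stance
    f_max_hz: float  # frequency of maximum energy, Hz


def analytic_signal(imf: np.ndarray, fs: float) -> AnalyticSignal:
    """Analytic signal of one IMF via the discrete Hilbert transform.

    Instantaneous frequency is the centered finite difference of the
    unwrapped phase (one-sided at the edges), in Hz.  Where the
    amplitude is numerically zero the frequency is set to 0 by
    convention.
    """
    imf = np.asarray(imf, dtype=np.float64)
    if len(imf) < 8:
        raise ValueError("IMF too short for Hilbert analysis")
    z = hilbert(imf)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    freq = np.where(amp < _AMP_EPS, 0.0, freq)
    return AnalyticSignal(amplitude=amp, phase=phase, inst_freq=freq, fs=fs)


def hilbert_spectrum(
    imfset: IMFSet,
    fs: float,
    freq_bin_width: float = 1.0,
    fmax: float = 500.0,
    t0: float = 0.0,
) -> HilbertSpectrum:
    """Build H(f, t) by depositing each IMF's a^2(t) at its f(t).

    Samples whose instantaneous frequency falls outside (0, fmax] are
    excluded (negative and super-Nyquist frequencies are edge artefacts
    of the Hilbert transform).  The residual is not included.
    """
    n_bins = int(round(fmax / freq_bin_width))
    n_t = imfset.source_length
    energy = np.zeros((n_bins, n_t))
    for imf in imfset.imfs:
        a = analytic_signal(imf, fs)
        f = a.inst_freq
        ok = (f > 0.0) & (f <= fmax)
        # bin i covers (i*w, (i+1)*w]
        bins = np.ceil(f[ok] / freq_bin_width).astype(np.int64) - 1
        np.add.at(energy, (bins, np.flatnonzero(ok)), a.amplitude[ok] ** 2)
    edges = np.arange(n_bins + 1) * freq_bin_width
    return HilbertSpectrum(energy=energy, freq_edges=edges, fs=fs, t0=t0)


def marginal_spectrum(hs: HilbertSpectrum) -> np.ndarray:
    """Marginal Hilbert spectrum h(f): total energy per frequency bin."""
    return hs.energy.sum(axis=1)


def locate_max_energy(
    hs: HilbertSpectrum,
    seg: StanceSegment,
    smooth_hz: float = 5.0,
    smooth_s: float = 0.010,
) -> SpectralFeatures:
    """Timing and frequency of the stance-phase energy maximum.

    The energy matrix is first smoothed with a small moving-average
    kernel (default 5 Hz x 10 ms) so the argmax is not dominated by a
    single noisy sample; the argmax is then taken over stance columns
    only.  Ties break toward the earliest time, then the lowest
    frequency.  Returns S_max as % of stance and F_max as the bin
    center in Hz.
    """
    kf = max(1, int(round(smooth_hz / hs.bin_width)))
    kt = max(1, int(round(smooth_s * hs.fs)))
    smoothed = ndimage.uniform_filter(hs.energy, size=(kf, kt), mode="nearest")
    stance = smoothed[:, seg.onset_index : seg.offset_index + 1]
    if not np.any(stance > 0):
        raise UndefinedFeaturesError("no spectral energy within the stance phase")
    # row-major argmax over [time, freq] -> earliest time, then lowest bin
    flat = int(np.argmax(stance.T))
    t_idx, f_idx = divmod(flat, stance.shape[0])
    s_max = 100.0 * t_idx / (seg.n_stance - 1)
    return SpectralFeatures(s_max_pct=float(s_max), f_max_hz=float(hs.bin_centers[f_idx]))


def band_power(
    hs: HilbertSpectrum, band: tuple[float, float], window: tuple[int, int]
) -> float:
    """Total energy in a (low, high] frequency band over a sample window.

    ``window`` is a half-open sample range [start, stop).  A bin is
    included when its interval lies entirely inside the band.
    """
    start, stop = window
    start = max(int(start), 0)
    stop = min(int(stop), hs.energy.shape[1])
    if stop <= start:
        raise ValueError(f"empty analysis window [{window[0]}, {window[1]})")
    low, high = band
    in_band = (hs.freq_edges[:-1] >= low) & (hs.freq_edges[1:] <= high)
    return float(hs.energy[in_band, start:stop].sum())


def analysis_windows(seg: StanceSegment, fs: float) -> dict[str, tuple[int, int]]:
    """The three study windows as half-open sample ranges.

    ``pre``: the 100 ms (absolute, not % of stance) before contact;
    ``early``: the first 20% of stance; ``mid``: 20-40% of stance.
    """
    onset = seg.onset_index
    n = seg.n_stance
    return {
        "pre": (onset - seg.pre_window_samples, onset),
        "early": (onset, onset + int(round(0.20 * n))),
        "mid": (onset + int(round(0.20 * n)), onset + int(round(0.40 * n))),
    }


def normalize_band_power(raw: "np.ndarray | list[float]") -> np.ndarray:
    """Express band powers as % of the maximum within a group.

    Applied per (subject, muscle, window, band) group across the three
    foot-strike conditions; an all-zero group returns zeros with a
    warning.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.size == 0 or np.any(arr < 0):
        raise ValueError("band powers must be a nonempty nonnegative collection")
    top = arr.max()
    if top == 0:
        warnings.warn("all band powers zero in normalization group", stacklevel=2)
        return np.zeros_like(arr)
    return 100.0 * arr / top
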