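"""EMG conditioning: band-pass filtering, RMS enveloping, stance detection,
time normalization and reference-based amplitude normalization.

The processing chain mirrors standard surface-EMG practice for gait
studies: a fourth-order zero-phase Butterworth band-pass (10-450 Hz)
removes motion artefact and out-of-band noise, the rectified signal is
smoothed with a 50 ms moving RMS window, and each muscle's envelope is
expressed relative to the mean of the stance-phase peak RMS values from
that subject's three rearfoot-strike (RFS) trials.  Stance is segmented
from the vertical ground-reaction force with a 20 N contact threshold,
and stance time is normalized to 0-100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalTrace",
    "StanceSegment",
    "NoStanceError",
    "bandpass_filter",
    "moving_rms",
    "detect_stance",
    "normalize_rms",
    "time_normalize",
    "stance_peak",
]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        Sample values; stored as a float64 array.
    fs
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample in seconds, relative to an arbitrary
        reference (typically foot contact, so it may be negative).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains non-finite samples")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        return SignalTrace(samples, self.fs, self.t0)


class NoStanceError(ValueError):
    """Raised when a ground-reaction-force trace never crosses the
    contact threshold, so no stance phase can be segmented."""


@dataclass(frozen=True)
class StanceSegment:
    """Stance-phase endpoints plus the pre-contact analysis window.

    ``onset_index``/``offset_index`` are the first/last samples at or
    above the contact threshold.  ``pre_window_samples`` is the length
    of the pre-contact window (100 ms worth of samples by default);
    ``truncated`` flags the degenerate case where that window would
    extend before the start of the trace.
    """

    onset_index: int
    offset_index: int
    pre_window_samples: int
    truncated: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.offset_index <= self.onset_index:
            raise ValueError("stance offset must come after onset")

    @property
    def n_stance(self) -> int:
        """Number of samples spanned by stance (onset..offset inclusive)."""
        return self.offset_index - self.onset_index + 1


def bandpass_filter(
    trace: SignalTrace, low: float = 10.0, high: float = 450.0, order: int = 4
) -> SignalTrace:
    """Zero-phase Butterworth band-pass filter.

    A filter of the given order is designed and applied forward and
    backward (``sosfiltfilt``), which cancels phase distortion at the
    cost of doubling the effective attenuation slope.  The DC component
    is removed by construction.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= trace.fs / 2:
        raise ValueError(
            f"high cut-off {high} Hz must be below the Nyquist rate {trace.fs / 2} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    return trace.with_samples(sps.sosfiltfilt(sos, trace.samples))


def moving_rms(trace: SignalTrace, window: float = 0.050) -> SignalTrace:
    """Centered moving root-mean-square envelope.

    Full-wave rectification is absorbed by the squaring.  Windows are
    shrunk symmetrically at the trace edges so the output has the same
    length as the input.
    """
    n = len(trace)
    w = int(round(window * trace.fs))
    if w < 2:
        raise ValueError(f"window of {window} s is under 2 samples at fs={trace.fs}")
    if w > n:
        raise ValueError(f"window ({w} samples) longer than trace ({n} samples)")
    sq = np.abs(trace.samples) ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    idx = np.arange(n)
    left = np.maximum(idx - (w - 1) // 2, 0)
    right = np.minimum(idx + w // 2, n - 1)
    mean_sq = (csum[right + 1] - csum[left]) / (right - left + 1)
    return trace.with_samples(np.sqrt(mean_sq))


def detect_stance(
    grf: SignalTrace, threshold: float = 20.0, pre_window: float = 0.100
) -> StanceSegment:
    """Segment the stance phase from a vertical GRF trace.

    The longest contiguous run of samples at or above ``threshold``
    (newtons) is taken as stance; its first and last samples are the
    onset and offset.  The pre-contact window is ``pre_window`` seconds
    before the onset, flagged as truncated if it would start before the
    trace does.
    """
    above = grf.samples >= threshold
    if not above.any():
        raise NoStanceError(f"GRF never reaches the {threshold} N contact threshold")
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0] if above[0] else [], edges[~above[edges]] + 1]).astype(int)
    ends = np.concatenate([edges[above[edges]], [len(above) - 1] if above[-1] else []]).astype(int)
    lengths = ends - starts + 1
    k = int(np.argmax(lengths))
    onset, offset = int(starts[k]), int(ends[k])
    pre = int(round(pre_window * grf.fs))
    truncated = onset - pre < 0
    if truncated:
        pre = onset
    return StanceSegment(onset, offset, pre, truncated=truncated)


def normalize_rms(env: SignalTrace, reference: float) -> SignalTrace:
    """Express an RMS envelope as a fraction of a reference amplitude.

    The study convention is ``reference`` = the mean over a subject's
    three RFS trials of the stance-phase peak RMS, computed per muscle,
    so a value of 1.0 corresponds to 100% of the RFS reference level.
    """
    if reference <= 0:
        raise ValueError(f"normalization reference must be positive, got {reference}")
    return env.with_samples(env.samples / reference)


def stance_peak(env: SignalTrace, seg: StanceSegment) -> float:
    """Peak of an envelope within the stance phase."""
    return float(np.max(env.samples[seg.onset_index : seg.offset_index + 1]))


def time_normalize(env: SignalTrace, seg: StanceSegment, n_points: int = 101) -> np.ndarray:
    """Resample the stance-phase portion onto a 0-100% stance grid.

    Linear interpolation onto ``n_points`` equally spaced points between
    onset and offset (101 points = a conventional 1% grid).
    """
    if seg.offset_index <= seg.onset_index:
        raise ValueError("degenerate stance segment")
    src = np.arange(seg.onset_index, seg.offset_index + 1, dtype=float)
    dst = np.linspace(seg.onset_index, seg.offset_index, n_points)
    return np.interp(dst, src, env.samples[seg.onset_index : seg.offset_index + 1])
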