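"""Seeded synthetic gait EMG + GRF cohorts.

No public data accompanies the study design this package analyzes, so
testing end to end requires a generator that emulates its structure:
six lower-limb muscles (VM, VL, RF, TA, GM, GL) recorded at 1000 Hz
with a synchronized vertical ground-reaction force, three foot-strike
conditions (forefoot FFS, midfoot MFS, rearfoot RFS), 16 subjects x 3
trials per condition.

Each EMG channel is a Gaussian burst envelope in normalized stance
time modulating band-limited Gaussian noise in a low (15-60 Hz) and a
high (80-200 Hz) band, plus an optional pre-activation burst in the
100 ms before contact and white measurement noise.  Condition effects
are injected through per-muscle, per-condition burst parameters; the
defaults emulate the headline pattern of the study population: the
energy maximum of VM, VL, GM and GL arrives earlier in stance under
RFS, the gastrocnemii carry relatively more low-band power under
MFS/RFS at contact, and TA pre-activation (hence TA/GM co-activation)
is highest under RFS.

Between-subject variance is multiplicative: each subject draws
log-normal factors on the channel gains, producing the positive,
correlated repeated-measures structure real cohorts show.  All
randomness is keyed by ``(seed, subject, condition, trial)`` streams,
so cohorts are bit-reproducible and extending one dimension never
reshuffles another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocess import SignalTrace, bandpass_filter

__all__ = [
    "MUSCLES",
    "CONDITIONS",
    "BurstParams",
    "EffectDesign",
    "TrialRecord",
    "Cohort",
    "GRFResult",
    "generate_grf",
    "generate_emg_channel",
    "generate_cohort",
    "default_design",
    "write_cohort",
    "read_trial_csv",
]

MUSCLES = ("VM", "VL", "RF", "TA", "GM", "GL")
CONDITIONS = ("FFS", "MFS", "RFS")

#: Bands used for the synthetic carriers, chosen inside the study's
#: low (<=60 Hz) and high (61-200 Hz) analysis bands with margin for
#: filter roll-off.
_LOW_CARRIER = (15.0, 60.0)
_HIGH_CARRIER = (80.0, 200.0)

_CONTACT_THRESHOLD_N = 20.0


@dataclass(frozen=True)
class BurstParams:
    """Per-muscle, per-condition activation-burst parameters.

    burst_center and burst_width are fractions of stance in (0, 1);
    gains are dimensionless and nonnegative.
    """

    burst_center: float = 0.35
    burst_width: float = 0.18
    low_band_gain: float = 1.0
    high_band_gain: float = 1.0
    pre_activation_gain: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.burst_center < 1 or not 0 < self.burst_width < 1:
            raise ValueError("burst_center and burst_width must lie in (0, 1)")
        if min(self.low_band_gain, self.high_band_gain, self.pre_activation_gain) < 0:
            raise ValueError("gains must be nonnegative")


@dataclass(frozen=True)
class EffectDesign:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 16
    n_trials_per_condition: int = 3
    fs: float = 1000.0
    stance_duration: float = 0.25
    pre_window: float = 0.100
    lead_in: float = 0.150  # quiet time before contact, >= pre_window
    tail: float = 0.050  # quiet time after toe-off
    burst_params: dict[str, dict[str, BurstParams]] = field(default_factory=dict)
    noise_sd: float = 0.05
    subject_sd: float = 0.20  # sigma of log-normal per-subject gain factors
    center_jitter_sd: float = 0.02  # trial-level burst-center jitter (fraction)
    subject_center_sd: float = 0.02  # per-subject burst-center offset (fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.fs <= 2 * 450.0:
            raise ValueError("fs must exceed 900 Hz so the 10-450 Hz band is representable")
        if self.stance_duration <= 0:
            raise ValueError("stance_duration must be positive")
        if self.lead_in < self.pre_window:
            raise ValueError("lead_in must cover the pre-contact window")

    def params_for(self, muscle: str, condition: str) -> BurstParams:
        return self.burst_params.get(muscle, {}).get(condition, BurstParams())


class GRFResult(NamedTuple):
    """A vertical GRF trace plus the generator's ground-truth events."""

    trace: SignalTrace
    onset_index: int
    offset_index: int


@dataclass(frozen=True)
class TrialRecord:
    """One running trial: six EMG channels + GRF + metadata."""

    emg: dict[str, SignalTrace]
    grf: SignalTrace
    subject_id: str
    condition: str
    trial_index: int
    fs: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.grf)
        for name, tr in self.emg.items():
            if len(tr) != n or tr.fs != self.fs:
                raise ValueError(f"channel {name} does not match GRF length/rate")
        if np.any(self.grf.samples < 0):
            raise ValueError("GRF must be nonnegative")


@dataclass(frozen=True)
class Cohort:
    """Generated trials plus the ground truth used to create them."""

    trials: list[TrialRecord]
    design: EffectDesign
    truth: dict


def _stream(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in key]))


def generate_grf(
    stance_duration: float,
    fs: float,
    condition: str = "RFS",
    seed: int = 0,
    lead_in: float = 0.150,
    tail: float = 0.050,
    peak_n: float = 1600.0,
) -> GRFResult:
    """Synthetic vertical GRF: quiet lead-in, one smooth stance bump, quiet tail.

    The stance shape is the classic double-hump vertical GRF: a broad
    active peak near mid-stance plus a condition-dependent impact
    transient shortly after contact (large for RFS, absent for FFS).
    Edges are steep enough that the above-20 N support matches the
    nominal stance duration to within a couple of samples, and the true
    onset/offset sample indices are returned alongside the trace.
    """
    if stance_duration <= 0 or fs <= 0:
        raise ValueError("stance_duration and fs must be positive")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_lead = int(round(lead_in * fs))
    n_stance = int(round(stance_duration * fs))
    n_tail = int(round(tail * fs))
    rng = _stream(seed, 7)
    u = np.linspace(0.0, 1.0, n_stance)
    base = np.sin(np.pi * u) ** 0.75
    hump = 1.0 - 0.25 * np.exp(-(((u - 0.5) / 0.12) ** 2))  # mid-stance valley
    impact_gain = {"RFS": 0.45, "MFS": 0.20, "FFS": 0.0}[condition]
    impact = impact_gain * np.exp(-(((u - 0.12) / 0.045) ** 2))
    amp = peak_n * (1.0 + 0.05 * rng.standard_normal())
    bump = amp * base * (hump + impact)
    # smooth within-stance physiological variability, zero at the edges
    wobble = 0.02 * amp * np.sin(2 * np.pi * rng.uniform(1.5, 3.5) * u + rng.uniform(0, 2 * np.pi))
    bump = np.maximum(bump + wobble * np.sin(np.pi * u), 0.0)
    samples = np.concatenate([np.zeros(n_lead), bump, np.zeros(n_tail)])
    above = np.flatnonzero(samples >= _CONTACT_THRESHOLD_N)
    trace = SignalTrace(samples, fs, t0=-lead_in)
    return GRFResult(trace=trace, onset_index=int(above[0]), offset_index=int(above[-1]))


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (Butterworth filtered)."""
    white = rng.standard_normal(n)
    filtered = bandpass_filter(SignalTrace(white, fs), band[0], band[1], order=4).samples
    sd = np.std(filtered)
    return filtered / sd if sd > 0 else filtered


def generate_emg_channel(
    params: BurstParams,
    n_samples: int,
    onset: int,
    stance_samples: int,
    fs: float,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[SignalTrace, dict]:
    """One synthetic EMG channel with a known activation burst.

    The stance burst is a Gaussian envelope in normalized stance time
    (center/width from ``params``) modulating a mix of low-band
    (15-60 Hz) and high-band (80-200 Hz) noise carriers; the
    pre-activation burst occupies the 100 ms before ``onset`` with the
    same carrier mix scaled by ``pre_activation_gain``; white
    measurement noise of sd ``noise_sd`` is added on top.  Returns the
    zero-mean trace and a ground-truth dict (burst center in % stance,
    onset index).
    """
    if not 0 <= onset < n_samples:
        raise ValueError(f"onset {onset} outside trace of {n_samples} samples")
    rng = _stream(seed, 11)
    t_idx = np.arange(n_samples, dtype=float)
    u = (t_idx - onset) / stance_samples  # normalized stance time
    env = np.exp(-0.5 * ((u - params.burst_center) / params.burst_width) ** 2)
    env[t_idx < onset] = 0.0  # stance burst starts at contact
    pre_len = int(round(0.100 * fs))
    pre_env = np.exp(-0.5 * ((t_idx - (onset - 0.5 * pre_len)) / (0.25 * pre_len)) ** 2)
    pre_env[t_idx >= onset] = 0.0

    total_gain = params.low_band_gain + params.high_band_gain
    if total_gain > 0:
        wl = params.low_band_gain / total_gain
        wh = params.high_band_gain / total_gain
    else:
        wl = wh = 0.0
    carrier = np.zeros(n_samples)
    if params.low_band_gain > 0:
        carrier += params.low_band_gain * _band_noise(n_samples, fs, _LOW_CARRIER, rng)
    if params.high_band_gain > 0:
        carrier += params.high_band_gain * _band_noise(n_samples, fs, _HIGH_CARRIER, rng)
    pre_carrier = np.zeros(n_samples)
    if params.pre_activation_gain > 0 and total_gain > 0:
        if wl > 0:
            pre_carrier += wl * _band_noise(n_samples, fs, _LOW_CARRIER, rng)
        if wh > 0:
            pre_carrier += wh * _band_noise(n_samples, fs, _HIGH_CARRIER, rng)
    x = env * carrier + params.pre_activation_gain * pre_env * pre_carrier
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n_samples)
    if x.any():
        x = x - x.mean()
    truth = {
        "burst_center_pct": 100.0 * params.burst_center,
        "onset_index": onset,
        "stance_samples": stance_samples,
    }
    return SignalTrace(x, fs, t0=-onset / fs), truth


def default_design(**overrides) -> EffectDesign:
    """The study-emulating cohort design.

    16 subjects x 3 conditions x 3 trials at 1000 Hz with a 250 ms
    stance.  Condition effects: the VM/VL/GM/GL burst centers arrive
    15% of stance earlier under RFS; GM carries more low-band and less
    high-band power under MFS/RFS; TA pre-activation grows from FFS to
    RFS while gastrocnemius pre-activation is largest under FFS.
    """
    bp: dict[str, dict[str, BurstParams]] = {}

    def set_params(muscle, **per_condition):
        bp[muscle] = {c: per_condition[c] for c in CONDITIONS}

    quad_early = {
        "FFS": BurstParams(burst_center=0.40),
        "MFS": BurstParams(burst_center=0.40),
        "RFS": BurstParams(burst_center=0.25),
    }
    set_params("VM", **quad_early)
    set_params("VL", **quad_early)
    set_params(
        "RF",
        FFS=BurstParams(burst_center=0.35),
        MFS=BurstParams(burst_center=0.35),
        RFS=BurstParams(burst_center=0.35),
    )
    set_params(
        "TA",
        FFS=BurstParams(burst_center=0.30, pre_activation_gain=0.30),
        MFS=BurstParams(burst_center=0.30, pre_activation_gain=0.60),
        RFS=BurstParams(burst_center=0.30, pre_activation_gain=0.90),
    )
    set_params(
        "GM",
        FFS=BurstParams(burst_center=0.45, low_band_gain=0.7, high_band_gain=1.2,
                        pre_activation_gain=0.80),
        MFS=BurstParams(burst_center=0.45, low_band_gain=1.2, high_band_gain=0.8,
                        pre_activation_gain=0.40),
        RFS=BurstParams(burst_center=0.30, low_band_gain=1.2, high_band_gain=0.8,
                        pre_activation_gain=0.35),
    )
    set_params(
        "GL",
        FFS=BurstParams(burst_center=0.45, pre_activation_gain=0.70),
        MFS=BurstParams(burst_center=0.45, pre_activation_gain=0.40),
        RFS=BurstParams(burst_center=0.30, pre_activation_gain=0.35),
    )
    return EffectDesign(burst_params=bp, **overrides)


def generate_cohort(design: EffectDesign, muscles: tuple[str, ...] = MUSCLES) -> Cohort:
    """Generate the full cohort of trials described by ``design``.

    Per subject, a log-normal factor (sigma = ``design.subject_sd``)
    multiplies every channel gain, and a normal offset
    (sd = ``design.subject_center_sd``) shifts every burst center;
    trial-level center jitter (sd = ``design.center_jitter_sd``) adds
    within-cell variance.  Ground-truth per-condition burst centers and
    injected between-condition differences are stored on the cohort.
    """
    trials: list[TrialRecord] = []
    n_stance = int(round(design.stance_duration * design.fs))
    truth: dict = {"subjects": {}, "design_centers_pct": {}}
    for m in muscles:
        truth["design_centers_pct"][m] = {
            c: 100.0 * design.params_for(m, c).burst_center for c in CONDITIONS
        }
    for si in range(design.n_subjects):
        subject_id = f"S{si + 1:02d}"
        srng = _stream(design.seed, 1, si)
        gain_factor = {m: float(np.exp(design.subject_sd * srng.standard_normal())) for m in muscles}
        center_offset = {m: float(design.subject_center_sd * srng.standard_normal()) for m in muscles}
        truth["subjects"][subject_id] = {"gain_factor": gain_factor, "center_offset": center_offset}
        for ci, cond in enumerate(CONDITIONS):
            for ti in range(design.n_trials_per_condition):
                trial_seed = _stream(design.seed, 2, si, ci, ti).integers(0, 2**31 - 1)
                grf = generate_grf(
                    design.stance_duration, design.fs, cond, seed=int(trial_seed),
                    lead_in=design.lead_in, tail=design.tail,
                )
                n_samples = len(grf.trace)
                jrng = _stream(design.seed, 3, si, ci, ti)
                emg: dict[str, SignalTrace] = {}
                channel_truth: dict[str, dict] = {}
                for mi, m in enumerate(muscles):
                    p = design.params_for(m, cond)
                    center = p.burst_center + center_offset[m] + design.center_jitter_sd * jrng.standard_normal()
                    center = float(np.clip(center, 0.05, 0.95))
                    g = gain_factor[m]
                    p_trial = replace(
                        p,
                        burst_center=center,
                        low_band_gain=p.low_band_gain * g,
                        high_band_gain=p.high_band_gain * g,
                        pre_activation_gain=p.pre_activation_gain * g,
                    )
                    ch_seed = _stream(design.seed, 4, si, ci, ti, mi).integers(0, 2**31 - 1)
                    tr, ch_truth = generate_emg_channel(
                        p_trial, n_samples, grf.onset_index, n_stance,
                        design.fs, seed=int(ch_seed), noise_sd=design.noise_sd,
                    )
                    emg[m] = tr
                    channel_truth[m] = ch_truth
                trials.append(
                    TrialRecord(
                        emg=emg, grf=grf.trace, subject_id=subject_id,
                        condition=cond, trial_index=ti, fs=design.fs,
                        truth={
                            "grf_onset_index": grf.onset_index,
                            "grf_offset_index": grf.offset_index,
                            "channels": channel_truth,
                        },
                    )
                )
    return Cohort(trials=trials, design=design, truth=truth)


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort(cohort: Cohort, out_dir: "str | Path") -> Path:
    """Write one CSV per trial plus a manifest and a ground-truth sidecar.

    Trial files have columns time_s, VM, VL, RF, TA, GM, GL, GRF_N.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.trials:
        fname = f"{rec.subject_id}_{rec.condition}_t{rec.trial_index}.csv"
        cols = {"time_s": rec.grf.time}
        for m in MUSCLES:
            if m in rec.emg:
                cols[m] = rec.emg[m].samples
        cols["GRF_N"] = rec.grf.samples
        pd.DataFrame(cols).to_csv(out / fname, index=False, float_format="%.6g")
        rows.append(
            {"file": fname, "subject": rec.subject_id, "condition": rec.condition,
             "trial_index": rec.trial_index, "fs": rec.fs}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return manifest


def read_trial_csv(path: "str | Path", subject: str, condition: str, trial_index: int) -> TrialRecord:
    """Read one trial CSV back into a TrialRecord."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = float(round(1.0 / np.median(np.diff(t))))
    t0 = float(t[0])
    emg = {m: SignalTrace(df[m].to_numpy(), fs, t0) for m in MUSCLES if m in df.columns}
    grf = SignalTrace(np.maximum(df["GRF_N"].to_numpy(), 0.0), fs, t0)
    return TrialRecord(emg=emg, grf=grf, subject_id=subject, condition=condition,
                       trial_index=int(trial_index), fs=fs)
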