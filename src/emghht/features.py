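"""Per-trial scalar features: windowed RMS, S_max/F_max, band powers,
and the tibialis-anterior / medial-gastrocnemius co-activation index.

The co-activation index follows the agonist/antagonist convention

    CI = 2 * EMG_TA / (EMG_GM + EMG_TA) * 100,

where EMG_TA and EMG_GM are normalized RMS amplitudes summarized over
an analysis window; CI = 100% means perfectly balanced dorsiflexor /
plantar-flexor activation, CI > 100% means the antagonist (TA)
dominates.

``build_feature_table`` runs the whole chain per muscle per trial:
band-pass -> ensemble EMD -> residual-free reconstruction -> moving
RMS (normalized to the subject's RFS reference) for amplitude
features, and Hilbert spectrum -> S_max/F_max + band powers for the
spectral features.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import EEMDConfig, IMFSet, eemd_decompose
from .preprocess import (
    SignalTrace,
    StanceSegment,
    bandpass_filter,
    detect_stance,
    moving_rms,
    stance_peak,
)
from .spectral import (
    HIGH_BAND,
    LOW_BAND,
    analysis_windows,
    band_power,
    hilbert_spectrum,
    locate_max_energy,
)
from .synthetic_data import TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "FeatureTable",
    "reconstruct_without_residual",
    "coactivation_index",
    "build_feature_table",
]

WINDOWS = ("pre", "early", "mid")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the per-trial feature pipeline."""

    filter_low_hz: float = 10.0
    filter_high_hz: float = 450.0
    filter_order: int = 4
    rms_window_s: float = 0.050
    stance_threshold_n: float = 20.0
    eemd: EEMDConfig = field(default_factory=EEMDConfig)
    freq_bin_width_hz: float = 1.0
    fmax_hz: float = 500.0
    ci_statistic: str = "mean"  # or "peak"
    seed: int = 0


@dataclass(frozen=True)
class FeatureTable:
    """Tidy per-trial features.

    ``features``: one row per (subject, condition, trial, muscle,
    window) with rms_pct (window mean of the RFS-normalized envelope,
    %), s_max_pct / f_max_hz (whole-stance values, repeated across the
    trial's windows), p_low / p_high (raw band powers) and p_low_pct /
    p_high_pct (as % of the per-subject x muscle x window x band
    maximum across conditions).

    ``ci``: one row per (subject, condition, trial, window) with
    ci_pct.

    ``failures``: trials that could not be processed, with reasons.
    """

    features: pd.DataFrame
    ci: pd.DataFrame
    failures: pd.DataFrame


def reconstruct_without_residual(imfset: IMFSet) -> np.ndarray:
    """Sum of all IMFs, excluding the residual trend.

    Dropping the residual removes slow drift (baseline wander) before
    RMS amplitude features are computed.
    """
    if imfset.n_imfs == 0:
        warnings.warn("empty IMF set; reconstruction is all-zero", stacklevel=2)
        return np.zeros(imfset.source_length)
    return imfset.imfs.sum(axis=0)


def coactivation_index(emg_ta: float, emg_gm: float) -> float:
    """CI = 2*TA / (GM + TA) * 100, in percent (range 0-200)."""
    if emg_ta < 0 or emg_gm < 0:
        raise ValueError("window RMS amplitudes must be nonnegative")
    if emg_ta == 0 and emg_gm == 0:
        raise ValueError("co-activation undefined when both muscles are silent")
    # clamp float round-off; the ratio is mathematically within [0, 200]
    return float(np.clip(200.0 * emg_ta / (emg_gm + emg_ta), 0.0, 200.0))


def _window_stat(env: np.ndarray, window: tuple[int, int], stat: str) -> float:
    lo, hi = max(window[0], 0), min(window[1], len(env))
    if hi <= lo:
        return float("nan")
    seg = env[lo:hi]
    return float(seg.max() if stat == "peak" else seg.mean())


def _process_trial(
    rec: TrialRecord, config: FeatureConfig, muscles: tuple[str, ...]
) -> tuple[StanceSegment, dict[str, dict]]:
    """Envelope + spectral features for every requested muscle of one trial."""
    seg = detect_stance(rec.grf, config.stance_threshold_n)
    out: dict[str, dict] = {}
    windows = analysis_windows(seg, rec.fs)
    for mi, m in enumerate(muscles):
        filtered = bandpass_filter(
            rec.emg[m], config.filter_low_hz, config.filter_high_hz, config.filter_order
        )
        member_seed = int(
            np.random.SeedSequence(
                [config.seed & 0x7FFFFFFF, zlib.crc32(rec.subject_id.encode()) & 0xFFFF,
                 {"FFS": 0, "MFS": 1, "RFS": 2}.get(rec.condition, 3),
                 rec.trial_index, mi]
            ).generate_state(1)[0] & 0x7FFFFFFF
        )
        imfset = eemd_decompose(
            filtered,
            EEMDConfig(
                noise_sd_factor=config.eemd.noise_sd_factor,
                ensemble_size=config.eemd.ensemble_size,
                sift_iterations=config.eemd.sift_iterations,
                max_imfs=config.eemd.max_imfs,
                seed=member_seed,
            ),
        )
        recon = reconstruct_without_residual(imfset)
        env = moving_rms(SignalTrace(recon, rec.fs), config.rms_window_s)
        hs = hilbert_spectrum(imfset, rec.fs, config.freq_bin_width_hz, config.fmax_hz)
        sf = locate_max_energy(hs, seg)
        powers = {
            w: {
                "p_low": band_power(hs, LOW_BAND, windows[w]),
                "p_high": band_power(hs, HIGH_BAND, windows[w]),
            }
            for w in WINDOWS
        }
        out[m] = {
            "envelope": env,
            "peak": stance_peak(env, seg),
            "s_max_pct": sf.s_max_pct,
            "f_max_hz": sf.f_max_hz,
            "powers": powers,
            "windows": windows,
        }
    return seg, out


def build_feature_table(
    cohort: "list[TrialRecord]",
    config: FeatureConfig | None = None,
    muscles: tuple[str, ...] | None = None,
) -> FeatureTable:
    """Run the full analysis chain over a cohort of trials.

    Amplitude normalization follows the study convention: for each
    subject x muscle, the reference is the mean over that subject's RFS
    trials of the stance-phase peak RMS envelope.  Band powers are
    additionally expressed per subject x muscle x window x band as % of
    the maximum across conditions.  Trials that fail stance detection
    or feature extraction are recorded in ``failures`` and skipped.
    """
    config = config or FeatureConfig()
    if muscles is None:
        muscles = tuple(cohort[0].emg.keys()) if cohort else ()
    processed: list[tuple[TrialRecord, StanceSegment, dict]] = []
    failures: list[dict] = []
    for rec in cohort:
        try:
            seg, per_muscle = _process_trial(rec, config, muscles)
        except Exception as exc:  # noqa: BLE001 - per-trial failures are data, not bugs
            logger.warning("trial %s/%s/%d failed: %s", rec.subject_id, rec.condition,
                           rec.trial_index, exc)
            failures.append(
                {"subject": rec.subject_id, "condition": rec.condition,
                 "trial_index": rec.trial_index, "error": str(exc)}
            )
            continue
        processed.append((rec, seg, per_muscle))

    # RFS reference per subject x muscle: mean stance-phase peak RMS
    ref: dict[tuple[str, str], float] = {}
    for rec, seg, per_muscle in processed:
        if rec.condition != "RFS":
            continue
        for m in muscles:
            ref.setdefault((rec.subject_id, m), []).append(per_muscle[m]["peak"])
    ref = {k: float(np.mean(v)) for k, v in ref.items()}

    feat_rows: list[dict] = []
    ci_rows: list[dict] = []
    for rec, seg, per_muscle in processed:
        norm_env: dict[str, np.ndarray] = {}
        for m in muscles:
            r = ref.get((rec.subject_id, m))
            if r is None or r <= 0:
                logger.warning("no RFS reference for %s/%s; skipping normalization",
                               rec.subject_id, m)
                norm_env[m] = np.full(len(per_muscle[m]["envelope"].samples), np.nan)
            else:
                norm_env[m] = per_muscle[m]["envelope"].samples / r
        windows = per_muscle[muscles[0]]["windows"]
        for m in muscles:
            for w in WINDOWS:
                feat_rows.append(
                    {
                        "subject": rec.subject_id, "condition": rec.condition,
                        "trial_index": rec.trial_index, "muscle": m, "window": w,
                        "rms_pct": 100.0 * _window_stat(norm_env[m], windows[w], "mean"),
                        "s_max_pct": per_muscle[m]["s_max_pct"],
                        "f_max_hz": per_muscle[m]["f_max_hz"],
                        "p_low": per_muscle[m]["powers"][w]["p_low"],
                        "p_high": per_muscle[m]["powers"][w]["p_high"],
                    }
                )
        if "TA" in muscles and "GM" in muscles:
            for w in WINDOWS:
                ta = _window_stat(norm_env["TA"], windows[w], config.ci_statistic)
                gm = _window_stat(norm_env["GM"], windows[w], config.ci_statistic)
                try:
                    ci = coactivation_index(ta, gm)
                except ValueError:
                    ci = float("nan")
                ci_rows.append(
                    {"subject": rec.subject_id, "condition": rec.condition,
                     "trial_index": rec.trial_index, "window": w, "ci_pct": ci}
                )

    features = pd.DataFrame(feat_rows)
    if not features.empty:
        for col, raw in (("p_low_pct", "p_low"), ("p_high_pct", "p_high")):
            group_max = features.groupby(["subject", "muscle", "window"])[raw].transform("max")
            with np.errstate(invalid="ignore", divide="ignore"):
                features[col] = np.where(
                    group_max > 0, 100.0 * features[raw] / group_max, 0.0
                )
    return FeatureTable(
        features=features,
        ci=pd.DataFrame(ci_rows),
        failures=pd.DataFrame(failures, columns=["subject", "condition", "trial_index", "error"]),
    )
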