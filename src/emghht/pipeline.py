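"""End-to-end orchestration: simulate -> analyze -> stats.

A :class:`RunConfig` aggregates every stage's parameters (the defaults
reproduce the study settings: 10-450 Hz band-pass, 50 ms RMS window,
20 N contact threshold, Nstd = 0.2, NE = 100, 10 sifts) plus the
cohort design and a master seed.  ``run_pipeline`` writes features.csv,
ci.csv, stats.csv, qc.csv and run_meta.json into an output directory;
reruns with an identical config hash reproduce the outputs
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import EEMDConfig
from .features import FeatureConfig, FeatureTable, build_feature_table
from .stats import condition_stats_table
from .synthetic_data import (
    BurstParams,
    Cohort,
    EffectDesign,
    TrialRecord,
    default_design,
    generate_cohort,
    read_trial_csv,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "run_stats", "load_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one schema-validated object."""

    filter_low_hz: float = 10.0
    filter_high_hz: float = 450.0
    filter_order: int = 4
    rms_window_s: float = 0.050
    stance_threshold_n: float = 20.0
    eemd_noise_sd_factor: float = 0.2
    eemd_ensemble_size: int = 100
    eemd_sift_iterations: int = 10
    freq_bin_width_hz: float = 1.0
    fmax_hz: float = 500.0
    ci_statistic: str = "mean"
    n_subjects: int = 16
    n_trials_per_condition: int = 3
    fs: float = 1000.0
    stance_duration: float = 0.25
    seed: int = 0

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            filter_low_hz=self.filter_low_hz,
            filter_high_hz=self.filter_high_hz,
            filter_order=self.filter_order,
            rms_window_s=self.rms_window_s,
            stance_threshold_n=self.stance_threshold_n,
            eemd=EEMDConfig(
                noise_sd_factor=self.eemd_noise_sd_factor,
                ensemble_size=self.eemd_ensemble_size,
                sift_iterations=self.eemd_sift_iterations,
            ),
            freq_bin_width_hz=self.freq_bin_width_hz,
            fmax_hz=self.fmax_hz,
            ci_statistic=self.ci_statistic,
            seed=self.seed,
        )

    def design(self) -> EffectDesign:
        return default_design(
            n_subjects=self.n_subjects,
            n_trials_per_condition=self.n_trials_per_condition,
            fs=self.fs,
            stance_duration=self.stance_duration,
            seed=self.seed,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_YAML_KEYS = {
    "filter.low_hz": "filter_low_hz",
    "filter.high_hz": "filter_high_hz",
    "filter.order": "filter_order",
    "rms.window_s": "rms_window_s",
    "stance.threshold_n": "stance_threshold_n",
    "eemd.noise_sd_factor": "eemd_noise_sd_factor",
    "eemd.ensemble_size": "eemd_ensemble_size",
    "eemd.sift_iterations": "eemd_sift_iterations",
    "spectral.freq_bin_width_hz": "freq_bin_width_hz",
    "spectral.fmax_hz": "fmax_hz",
    "features.ci_statistic": "ci_statistic",
    "simulate.n_subjects": "n_subjects",
    "simulate.n_trials_per_condition": "n_trials_per_condition",
    "simulate.fs": "fs",
    "simulate.stance_duration": "stance_duration",
    "seed": "seed",
}


def load_config(path: "str | Path | None") -> RunConfig:
    """Read a RunConfig from nested YAML (dotted keys documented above)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def flatten(d, prefix=""):
        out = {}
        for k, v in d.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                out.update(flatten(v, key + "."))
            else:
                out[key] = v
        return out

    flat = flatten(raw)
    kwargs = {}
    for dotted, value in flat.items():
        if dotted not in _YAML_KEYS:
            raise ValueError(f"unknown config key {dotted!r}")
        kwargs[_YAML_KEYS[dotted]] = value
    return RunConfig(**kwargs)


def load_manifest(manifest_path: "str | Path") -> list[TrialRecord]:
    """Load trial CSVs listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except OSError as exc:
        raise IOError(f"cannot read manifest {manifest_path}: {exc}") from exc
    trials = []
    for _, row in manifest.iterrows():
        path = manifest_path.parent / row["file"]
        if not path.exists():
            raise IOError(f"trial file missing: {path}")
        trials.append(
            read_trial_csv(path, row["subject"], row["condition"], int(row["trial_index"]))
        )
    return trials


def run_stats(table: FeatureTable) -> pd.DataFrame:
    """Condition comparisons for every scalar feature in a FeatureTable."""
    frames = []
    feats = table.features
    if not feats.empty:
        for col in ("rms_pct", "p_low_pct", "p_high_pct"):
            frames.append(condition_stats_table(feats, col))
        whole = feats[feats["window"] == "early"]  # S_max/F_max are per-trial
        for col in ("s_max_pct", "f_max_hz"):
            frames.append(condition_stats_table(whole, col, by=("muscle",)))
    if not table.ci.empty:
        frames.append(condition_stats_table(table.ci, "ci_pct", by=("window",)))
    frames = [f for f in frames if not f.empty]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(
    config: RunConfig,
    out_dir: "str | Path",
    manifest: "str | Path | None" = None,
    write_trials: bool = False,
) -> Path:
    """Simulate (or load) a cohort, extract features, run the statistics.

    Returns the output directory.  Artifacts: features.csv, ci.csv,
    stats.csv, qc.csv (per-trial processing status) and run_meta.json
    (config, hash, seed, versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is not None:
        trials = load_manifest(manifest)
    else:
        cohort = generate_cohort(config.design())
        trials = cohort.trials
        if write_trials:
            write_cohort(cohort, out / "trials")
    table = build_feature_table(trials, config.feature_config())
    table.features.to_csv(out / "features.csv", index=False)
    table.ci.to_csv(out / "ci.csv", index=False)
    stats_df = run_stats(table)
    stats_df.to_csv(out / "stats.csv", index=False)
    qc = pd.DataFrame(
        [
            {"subject": t.subject_id, "condition": t.condition, "trial_index": t.trial_index,
             "n_samples": len(t.grf), "status": "ok"}
            for t in trials
        ]
    )
    if not table.failures.empty:
        failed = set(map(tuple, table.failures[["subject", "condition", "trial_index"]].to_numpy()))
        qc.loc[
            qc.apply(lambda r: (r.subject, r.condition, r.trial_index) in failed, axis=1),
            "status",
        ] = "failed"
    qc.to_csv(out / "qc.csv", index=False)
    meta = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "emghht": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_trials": len(trials),
        "n_failures": int(len(table.failures)),
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out
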