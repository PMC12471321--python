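# emghht

Ensemble empirical-mode-decomposition (EEMD) and Hilbert–Huang spectral
analysis of lower-limb surface EMG across running foot-strike patterns.

Surface EMG around foot–ground contact is short, non-stationary and
amplitude/frequency modulated, which defeats Fourier-based
time–frequency summaries. `emghht` is for movement scientists and
biomechanists who want the EEMD route instead: decompose each muscle's
stance-phase EMG into intrinsic mode functions, build the Hilbert
spectrum, and compare forefoot (FFS), midfoot (MFS) and rearfoot (RFS)
strike conditions on interpretable scalar features, subject-within.

## The method

EMD sifts a signal S(t) into intrinsic mode functions C_i(t) plus a
residual r_N(t),

    S(t) = Σ_i C_i(t) + r_N(t),

by repeatedly subtracting the mean of cubic-spline envelopes through
the local extrema (here: a fixed 10 sifting iterations per IMF). EEMD
stabilizes this against mode mixing by decomposing NE = 100 white-noise
perturbed copies (noise SD = 0.2 × signal SD, Nstd = 0.2) and averaging
IMFs index-wise. From each IMF's analytic signal z(t) = a(t)e^{iθ(t)}
the Hilbert spectrum H(f, t) collects a²(t) on the instantaneous
frequency–time plane; its stance-phase maximum gives the timing S_max
(% of stance) and frequency F_max (Hz) of peak energy, and band sums
give P_≤60Hz and P_61–200Hz over the 100 ms pre-contact, 0–20% and
20–40% stance windows. Amplitude features are 50 ms moving-RMS
envelopes of the residual-free reconstruction, normalized per subject ×
muscle to the mean RFS stance-phase peak. Ankle co-activation is

    CI = 2·EMG_TA / (EMG_GM + EMG_TA) × 100,

100% meaning balanced dorsiflexor/plantar-flexor drive. Features are
compared with one-way repeated-measures ANOVA and LSD post hoc tests.

Because no public recordings accompany this study design, the package
ships a seeded synthetic cohort generator (`emghht.synthetic_data`)
that emulates its structure — 16 subjects × 3 conditions × 3 trials,
six muscles (VM, VL, RF, TA, GM, GL) at 1000 Hz with a synchronized
vertical GRF — with known injected effects, so every pipeline stage is
testable and effect recovery can be measured. See `docs/methods.md`
for all modelling and numerical choices.

## Worked example

Generate a six-subject cohort, run the pipeline on TA and GM, and test
the injected GM timing effect:

```python
from emghht import (EEMDConfig, FeatureConfig, build_feature_table,
                    default_design, generate_cohort, rm_anova)

design = default_design(n_subjects=6, seed=42)
cohort = generate_cohort(design, muscles=("TA", "GM"))
table = build_feature_table(
    cohort.trials,
    FeatureConfig(eemd=EEMDConfig(ensemble_size=25), seed=42),
    muscles=("TA", "GM"),
)

gm = table.features.query("muscle == 'GM' and window == 'early'")
print(gm.groupby("condition").s_max_pct.mean().round(1))

cell = gm.pivot_table(index="subject", columns="condition",
                      values="s_max_pct", aggfunc="mean")
res = rm_anova(cell.to_numpy())
print(f"F({res.df_condition}, {res.df_error}) = {res.F:.1f}, p = {res.p:.2e}")

pre_ci = table.ci.query("window == 'pre'")
print(pre_ci.groupby("condition").ci_pct.mean().round(1))
```

Output:

```
condition
FFS    43.2
MFS    42.8
RFS    34.2
Name: s_max_pct, dtype: float64
F(2, 10) = 8.4, p = 7.36e-03
condition
FFS     63.5
MFS    119.8
RFS    138.1
Name: ci_pct, dtype: float64
```

The GM energy maximum arrives ~9 points of stance earlier under RFS
than under FFS/MFS (the generator injects an earlier RFS burst), and
the repeated-measures ANOVA detects it at p < 0.01. Pre-contact TA/GM
co-activation rises from FFS to RFS, reflecting the injected TA
pre-activation gradient — under RFS the antagonist TA dominates
(CI > 100%).

## Command line

```sh
emghht simulate --config cfg.yaml --out trials/        # cohort CSVs + manifest
emghht analyze  --manifest trials/manifest.csv --out run/
emghht stats    --features run/features.csv --ci run/ci.csv --out run/
emghht all      --out run/ --seed 1                    # simulate + analyze + stats
```

Trial CSVs have columns `time_s, VM, VL, RF, TA, GM, GL, GRF_N`; the
analysis writes `features.csv` (one row per subject × condition ×
trial × muscle × window: `rms_pct`, `s_max_pct`, `f_max_hz`, `p_low`,
`p_high` and their %-of-max normalizations), `ci.csv`, `stats.csv`
(F, p, LSD pairwise p per feature), `qc.csv` and `run_meta.json`
(config hash + versions; identical configs reproduce outputs
byte-for-byte). YAML config keys mirror the pipeline stages
(`filter.low_hz`, `rms.window_s`, `stance.threshold_n`,
`eemd.ensemble_size`, …); defaults are the study settings.

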