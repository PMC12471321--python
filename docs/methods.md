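# Methods

This note documents the models, algorithms and numerical choices behind
`emghht`, and what the synthetic cohort does and does not establish
about real data.

## Problem setting

Running foot-strike patterns (forefoot FFS, midfoot MFS, rearfoot RFS)
change how lower-limb muscles are recruited around foot–ground contact.
Surface EMG during the stance phase is non-stationary and amplitude- and
frequency-modulated, so classical Fourier or short-time methods smear
the very timing information of interest. The package implements the
ensemble empirical-mode-decomposition (EEMD) / Hilbert-spectral route:
decompose each muscle's stance-phase EMG into intrinsic mode functions
(IMFs), build the Hilbert spectrum H(f, t) from their analytic signals,
and summarize it by the stance time S_max and frequency F_max of maximum
energy, band powers below 60 Hz and in 61–200 Hz, RFS-normalized RMS
envelopes, and the tibialis-anterior / medial-gastrocnemius
co-activation index. Conditions are compared subject-within with
repeated-measures ANOVA and LSD post hoc tests.

## Preprocessing

* **Band-pass**: fourth-order Butterworth, 10–450 Hz, applied forward
  and backward (`sosfiltfilt`) for zero phase. Forward–backward
  application doubles the effective attenuation slope; the stated order
  refers to the designed filter, the conventional reading. Edge
  transients are controlled by scipy's default odd-reflection padding.
* **Envelope**: full-wave rectification followed by a centered 50 ms
  moving-RMS window (edges use symmetrically shrunken windows so length
  is preserved). A centered window is used because a trailing window
  would bias all timing summaries late by half a window; nothing in the
  analysis depends on causality.
* **Stance segmentation**: the vertical GRF's longest contiguous run of
  samples ≥ 20 N, a common gait-analysis contact threshold. The
  pre-contact window is an absolute 100 ms (not a stance percentage).
* **Amplitude normalization**: per subject × muscle, envelopes are
  divided by the mean over that subject's three RFS trials of the
  stance-phase *peak* of the smoothed envelope. The smoothed envelope
  (not the raw rectified signal) is the assumed reference basis, and
  normalization is per muscle; both choices make the whole feature set
  invariant to per-channel gain, which the tests verify end to end.
* **Time normalization**: stance is linearly resampled to a 101-point
  grid (1% resolution) when profiles are compared across trials.

## Decomposition

Plain EMD sifts each IMF with **exactly 10 envelope-mean subtractions**
(a fixed count, not an SD/Cauchy criterion). Envelopes are natural
cubic splines through the local extrema; extrema are strict
sign-changes of the first difference, with flat plateaus contributing
their midpoint (floored) once. The two extrema nearest each trace end
are mirrored about the endpoints before fitting, the standard remedy
for spline end swings. Extraction stops when the residual is constant,
monotone, or has at most one extremum, or at the dyadic bound
`floor(log2 n) − 1`. Completeness — signal = ΣIMF + residual — is
exact by telescoping.

EEMD decomposes `ensemble_size` (NE, default 100) copies of the signal
perturbed with white Gaussian noise of SD `noise_sd_factor` (Nstd,
default 0.2) times the signal SD, and averages IMFs index-wise. Two
choices here were genuinely open:

* **Member noise streams** are keyed by `(seed, member index)`, so
  enlarging the ensemble never reshuffles earlier members (tested).
* **Unequal IMF counts** across members are reconciled by zero-padding
  at the slow end, preserving the fast-IMF indexing the band analysis
  relies on.
* **The returned residual** is defined as `signal − Σ averaged IMFs`,
  which makes the completeness identity exact for EEMD as well; the
  alternative (averaging member residuals) leaves an O(Nstd/√NE)
  discrepancy with no analysis benefit.

Because sifting stops after a fixed 10 iterations, the textbook IMF
property (extrema and zero-crossing counts differing by at most one) is
only approximately enforced; the tests allow a difference of ≤ 2.

The sifting inner loops (extrema scan, tridiagonal natural-spline
solve, envelope evaluation) are compiled with numba; a full cohort run
performs tens of thousands of sifts and the compiled kernels keep one
EMD of a 450-sample trace under a millisecond.

## Spectral features

The analytic signal comes from the standard frequency-domain discrete
Hilbert transform; instantaneous frequency is the centered finite
difference of the unwrapped phase (one-sided at the edges), set to 0
where the amplitude is numerically zero. Energy is deposited as a²(t)
into 1 Hz × 1-sample cells; instantaneous frequencies outside
(0, 500] Hz — edge artefacts — are excluded, and the residual is never
included. The marginal spectrum is the time sum.

S_max/F_max are read from the stance-restricted spectrum after
smoothing with a 5 Hz × 10 ms moving-average kernel (configurable);
without smoothing a single noisy sample can capture the argmax. Ties
break toward the earliest time, then the lowest frequency. Band powers
use the half-open bands (0, 60] and (60, 200] Hz summed over the
pre-contact / 0–20% / 20–40% windows directly from H(f, t) (a windowed
marginal-spectrum route would give the same sums; the spectrum-window
route is the implementation). For presentation, band powers are
expressed per subject × muscle × window × band as a percentage of the
maximum across the three conditions.

## Co-activation

CI = 2·EMG_TA / (EMG_GM + EMG_TA) × 100, computed from the
RFS-normalized envelopes summarized over each analysis window. The
formula names no summary statistic; the window *mean* is the default
(configurable to peak). CI is clamped to its mathematical range
[0, 200] against float round-off. 100% is balanced dorsiflexor /
plantar-flexor activation; > 100% means the antagonist (TA) dominates.

## Statistics

One-way repeated-measures ANOVA per feature, trials averaged within
subject × condition first (standard for three-trial designs). The
classical decomposition SS_total = SS_condition + SS_subject + SS_error
gives F = MS_condition/MS_error on (k−1, (k−1)(n−1)) degrees of
freedom; sphericity is assumed and no correction applied. Perfectly
additive data (SS_error = 0 up to a 1e-10 relative tolerance) are
flagged degenerate and reported as p = 0 (or p = 1 when the condition
effect is also zero). Post hoc comparisons are Fisher's LSD:
t = Δmean/√(2·MS_error/n) at df_error, two-sided, unadjusted. Partial
eta squared SS_c/(SS_c+SS_e) is reported alongside.

## Synthetic cohort

The generator emulates the study's data structure: 16 subjects × 3
conditions × 3 trials, six muscles at 1000 Hz, one stance per trial.
Values the study design fixes (cohort shape, sampling rate, analysis
bands, windows) are taken as given; the remaining levels are realistic
choices documented here and not revisited:

* **Stance duration 250 ms** with a 150 ms quiet lead-in and 50 ms
  tail; the GRF is a double-hump vertical-force shape peaking near
  1600 N (≈ 2 body weights) with a condition-dependent impact transient
  (large for RFS, absent for FFS) and steep enough onset/offset that
  the 20 N support matches the nominal duration within ±2 samples.
* **EMG channels**: a Gaussian burst envelope in normalized stance time
  modulating band-limited Gaussian carriers at 15–60 Hz and 80–200 Hz
  (filtered with the same Butterworth design as preprocessing — no
  separate filter machinery), plus a pre-activation burst in the 100 ms
  before contact and white measurement noise (SD 0.05 of unit gain).
* **Injected effects** mirror the qualitative study findings: VM, VL,
  GM and GL burst centers at 40–45% of stance under FFS/MFS versus
  25–30% under RFS (the GM contrast, 45% vs 30%, is the headline
  recovery target); GM carries more low-band and less high-band power
  under MFS/RFS; TA pre-activation rises from FFS to RFS while
  gastrocnemius pre-activation is largest under FFS.
* **Variance structure**: per-subject log-normal gain factors
  (σ = 0.20) and normal burst-center offsets (σ = 0.02 of stance), with
  trial-level center jitter (σ = 0.02). The study reports no variance
  components to calibrate against, so these are free parameters chosen
  to give realistic repeated-measures correlation; they are documented,
  not fitted.

What passing tests show: the pipeline recovers injected timing and band
effects of the stated size under this noise model, with calibrated
type-I error. What they do not show: robustness to motion artefact,
electrode lift, heartbeat contamination, subject-specific spectral
shapes or non-Gaussian bursts — none of which the generator emulates.

## Problem sizes and determinism

The distributed test and acceptance runs use NE = 25 ensembles for
cohort-scale experiments and NE = 100 for single-signal checks, 20
cohort replicates for the timing-recovery experiment, 50 fixtures for
completeness and 1000 simulations for ANOVA calibration. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (design, seed) pairs yield
bit-identical cohorts, feature tables and CSV artifacts (covered by
tests).

## Known limitations

* Fixed-count sifting trades IMF orthodoxy for exact reproducibility of
  the stated procedure; mode mixing is only mitigated, not eliminated.
* Instantaneous frequency is unreliable where amplitude is near zero;
  such samples are excluded from the spectrum rather than repaired.
* No sphericity correction is applied (k = 3 conditions keeps the
  worst-case inflation modest); Mauchly/Shapiro–Wilk checks are left to
  standard tools.
* The CSV trial format is the only supported input; no C3D/EDF readers.
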