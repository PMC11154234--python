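# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Signal models

### IPFM beat generation and inversion

Beat times are generated (and, on analysis, read) under the integral pulse
frequency modulation model: beats fire when

Λ(t) = ∫₀ᵗ (1 + m(τ)) · HR_mean/60 dτ

crosses successive integers. The modulating signal is
`m(t) = a_RSA sin(2π f_R t) + a_LF sin(2π·0.1·t) + ν(t)`, with `ν` a
band-limited (< 0.9 Hz) noise of configurable standard deviation
representing broadband autonomic variability. A beat is placed at t = 0 and
crossings up to the record end are kept; a constant 60 bpm, 60 s record
therefore contains 61 beats at 0, 1, …, 60 s (the final crossing lands on
the end point and is included; the trailing partial interval is not
extrapolated).

On the analysis side the instantaneous heart rate is the derivative of a
cubic spline through the beat-count function k(t), evaluated on a 4 Hz
grid. The mean rate mHR is a zero-phase 4th-order Butterworth low-pass at
0.03 Hz, and HRV = HR − mHR exactly; a `normalized` flag yields the
modulating-signal estimate (HR − mHR)/mHR, which compensates the mean-rate
influence. An IPFM round trip (generate → detect → HRV) correlates with
the injected m(t) above r = 0.9 for modulation depths ≤ 0.1, which is the
package's core self-consistency check.

All very-low-frequency trend filters (ECG baseline at 0.03 Hz, mHR at
0.03 Hz) are zero-phase Butterworth rather than FIR: at these cutoffs a
linear-phase FIR with a usable transition band is longer than a 5-minute
record. The contract is unchanged (output = input − low-pass(input), no
phase distortion). The EDR band-pass (0.07–1 Hz) is a zero-phase
Kaiser-window FIR sized for ≥ 40 dB stop-band attenuation at 0.04 and
1.2 Hz.

### QRS synthesis and EDR ground truth

The QRS template is a three-Gaussian mixture (Q, R, S lobes; R sigma 6 ms,
giving an up-slope near 0.1 mV/ms for a 1 mV R wave). Smooth flanks give a
unique interior derivative maximum and are near-linear across the 8 ms
least-squares slope windows, so the generated slope series is analytically
controlled. Respiration multiplies the per-beat template amplitude by
(1 + d·resp(t_beat)), default depth d = 0.10, within the range of
respiratory ECG-morphology modulation seen in chest leads; an optional
width modulation exists but defaults off. Record SNR is defined as
10·log10(mean-square clean ECG / noise variance); benchmark records use
exactly 10 dB with noise band-limited below 45 Hz.

Down-slope fiducials maximize |l′| on [n_R, n_S] (the literal maximum of l′
would sit at the interval edge for an upright QRS). Argmax ties break to
the earliest sample. Slopes are reported in mV/ms so the R-wave-angle
constants 0.4 and 6.25 apply as printed; the formula then equals the angle
between lines of slopes I_US/2.5 and I_DS/2.5, an identity the test suite
checks to 1e-9.

### Respiratory-rate fusion

Welch spectra (40 s windows every 5 s; 12 s Hann sub-windows, 50% overlap;
zero-padded to a 4/1024 ≈ 0.0039 Hz grid, chosen to resolve the 0.025 Hz
accuracy target) are searched inside Ω_R = [F_R(k−1) − δ, F_R(k−1) + 2δ],
δ = 0.1 Hz. Candidate peaks must reach 85% of the global peak height; the
candidate nearest the previous estimate is selected. Peakness is the
percentage of Ω_R power within ±0.10 Hz of the selected peak. The window
half-width is matched to the ≈ 0.17 Hz main lobe of the 12 s Hann
sub-window: a ±0.05 Hz window cannot reach the 85% gate even for a
noiseless sinusoid (it tops out near 60%), which would silently disable the
fusion; ±0.10 Hz scores a clean tone at ~95–100% while a flat spectrum
scores ~66% and is still rejected. Both the width and the 85% threshold are
configurable.

Spectra qualify when peakness ≥ 85 (criterion A) and when, within their
window, their peakness (normalized to [0, 1]) is within λ = 0.05 of the
best signal (criterion B). Criterion B's alternative reading — total band
power within a fraction λ of the maximum — is available as
`criterion_b="power"`. Pooling is symmetric over windows k−2…k+2 (at most
5 spectra per EDR signal, 45 in total), with a causal mode (`causal=True`)
pooling k−4…k for streaming use. The new estimate is the argmax of the
fused spectrum *restricted to Ω_R*, which enforces the track-continuity
bound |ΔF_R| ≤ 2δ by construction; an empty selection holds the previous
fused spectrum and rate.

The track needs a predecessor at k = 0: the nine first-window largest-peak
locations are binned at 0.04 Hz and the median of the modal bin is used;
if no bin collects three votes, the argmax of the unit-normalized pooled
spectra decides. On the synthetic benchmark (rates 0.10–0.45 Hz, 10 dB SNR,
5-minute records) the worst-case steady-state error is well inside the
0.025 Hz design bound; `scripts/acceptance.py` recomputes it.

### Orthogonal subspace projection

The respiratory subspace V stacks the mean-centred respiration signal and
its delayed copies (default lags 0…40 samples = 10 s at 4 Hz; two-sided
delays optional). HRV is projected by least squares (`lstsq`
pseudoinverse, rcond 1e-10, which also covers rank-deficient V such as a
sinusoidal respiration of rank 2). P_R and P_⊥ are squared-norm fractions
and sum to 1 by orthogonality; residual LF/HF band powers integrate the
Welch PSD of HRV⊥ and are normalized by total HRV power by default
(`normalize_bands_by="residual"` switches the reference). The respiration
input defaults to the up-slope EDR of the detection lead; any EDR signal or
an external respiration trace can be substituted.

## Per-stage parameters

All nine parameters are computed over the final 240 s of each annotated
stage. Scalar statistics (median NN, IQR, RMSSD, pNN50) are computed once
over that window — no inner averaging. pNN50's denominator is the NN
interval count (with the conventional successive-difference count available
via `pnn50_denominator="differences"`). Ectopic correction flags intervals
deviating from a 5-interval running median by more than 30% and replaces
them value-wise by cubic-spline interpolation over the unflagged intervals;
a false detection splitting a 1.0 s interval yields two corrected ~1.0 s
intervals. The rule and threshold are configurable; more than 20% flagged
intervals raises a record-quality warning rather than an error.

## Statistics, classification, anomaly screening

Ratios R(Y_S) are tested against zero per stage (Shapiro–Wilk at 0.05 gates
paired t vs Wilcoxon); the across-stage omnibus is a repeated-measures
ANOVA when all four stage samples pass normality, otherwise Friedman, with
pairwise paired tests Bonferroni-corrected by the 6 comparisons. Under
exchangeable stages the corrected pairwise flag rate stays below 5%
(simulation in the test suite).

Classifier families use fixed, preset-style hyperparameters: LDA with
pooled covariance; SVM with Gaussian kernel, kernel scale √p (γ = 1/p),
box constraint 1; k-NN with cosine distance and k = 10; and a
subspace-discriminant ensemble of 30 closed-form pooled-covariance LDAs on
random ⌈p/2⌉-dimensional feature subspaces, predicting by vote. The k-NN
used on the leave-one-out hot path is a vectorized implementation whose
parity with `sklearn.neighbors.KNeighborsClassifier` is asserted in the
tests. Features are z-scored with training-fold statistics inside every
fold; each subject contributes one feature vector per member stage, so a
two-class task has two cases per subject and accuracy is
100·(TP + TN)/cases. Subjects missing any member stage are excluded from
that task. Wrapper selection is greedy forward search with full LOO at each
step and uniform-random tie-breaks under a caller seed.

The anomaly screen counts, per subject, incorrect cases over every
(family, feature-count) cell whose accuracy strictly exceeds 70%, optionally
accumulated across task pairs; a two-class pair offers 2 × 4 × 9 = 72
result slots per subject. Subjects exceeding a configurable count (default
20) are flagged; rankings are reported so callers can apply top-k cuts.

## Synthetic cohort: what it emulates, what it does not

Defaults model a 28-subject cohort, 6 anomalous, five 300 s stages, 3-lead
ECG at 500 Hz (the pipeline is validated at 2000 Hz as well; 500 Hz keeps
the default suites fast and is far above the fidelity needed by 8 ms slope
windows at the accuracy tested). Baselines: HR 70 ± 7 bpm, respiratory
rate 0.25 ± 0.04 Hz, RSA depth 0.05 ± 0.01, LF depth 0.03 ± 0.008,
broadband m-noise 0.02 — the last chosen so that successive-difference
statistics (pNN50) sit on a realistic continuum rather than collapsing to
0 under purely sinusoidal modulation.

Stage effects are multiplicative shifts versus baseline whose *directions*
follow the hyperbaric literature — heart rate falls with pressure (−10% at
5 atm), RSA/vagal modulation rises peaking at 5 atm (+45%), LF modulation
rises on descent (+40%) and falls on ascent (−20%), respiratory rate rises
slightly peaking on ascent — with magnitudes as package defaults (the
source studies report directions and significance, not effect sizes).
Intersubject variability scales each effect by N(1, 0.25). Anomalous
subjects oppose the trend with an exponent −(0.3 + |N(0, 1)|) drawn
independently per stage and parameter: every injected subject deviates
genuinely, but magnitudes are idiosyncratic, so the anomalous minority
neither forms a learnable cluster of its own nor preserves the cohort's
stage-ordering of effect magnitudes (either regularity would let a flexible
classifier identify their stages *correctly* and defeat the purpose of the
injection).

The generator does not emulate: realistic P/T-wave morphology (only what
EDR needs), pressure/temperature channels, electrode motion artefacts,
arrhythmias beyond isolated spurious/missed beats, or decompression
physiology. Passing tests therefore demonstrate correctness of the
algorithms under controlled cardiorespiratory coupling, not field
performance on clinical recordings.

## Problem sizes and degenerate inputs

Default suites use 5-minute stages, 28-subject cohorts and 20-seed repeats
for cohort-level claims; the respiratory benchmark runs 8 rates × 10 seeds.
Degenerate inputs are defined errors, not crashes: empty beat sets warn and
return empty annotations; constant respiration cannot form a subspace;
zero-power HRV windows cannot be normalized; sub-minimum interval counts
(30 per stage window) and sub-10-beat EDR series raise. A denominator of
zero in the baseline ratio is flagged missing and excludes the subject from
affected tasks, mirroring the missing-stage exclusion rule.

## Known limitations

- The ectopic-correction rule is a documented stand-in with a configurable
  threshold; it is not fitted to any reference implementation.
- The fusion initialization (majority vote over first-window peaks) can
  lock onto a harmonic if the first 40 s are atypically noisy; the track
  recovers only as fast as Ω_R allows (0.2 Hz per 5 s step upward).
- The subspace-discriminant ensemble is a preset-equivalent design; exact
  correspondence to any external tool's ensemble is not claimed.
- Beat detection is validated on synthetic morphology only (sensitivity and
  precision ≥ 99% at 10 dB SNR there); clinical-grade detectors should be
  substituted for real recordings via the `BeatAnnotations` contract.
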