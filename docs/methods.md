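# Methods

This note documents the models, estimators and numerical choices behind
`megpac`, and what validation on its synthetic cohorts does and does not
establish.

## Generative model

Each simulated trial is

    x(t) = A_α(t)·cos(φ_α(t)) + g(t)·cos(2π f_γ t + ψ₀) + σ·n_{1/f}(t),
    φ_α(t) = 2π f_α t + φ₀,
    g(t)   = A_γ(t) · (1 + m(t)·cos(φ_α(t) − φ_pref)) / √(1 + m(t)²/2),

sampled at `fs_raw` (default 1000 Hz) over a padded epoch
[−(1.5+2.5), +(1.5+2.5)] s around stimulus onset. Amplitudes and the
coupling depth switch from baseline to stimulus values at t = 0 while the
carrier phases stay continuous; φ₀ and ψ₀ are redrawn per trial, so the
gamma response is *induced* (it survives trial-averaged power but cancels
in the averaged waveform). The background `n_{1/f}` is spectrally shaped
Gaussian noise (PSD ∝ 1/f^β, unit variance, β = 1 by default).

Because the mean square of `1 + m·cos` over alpha cycles is `1 + m²/2`,
the RMS normalisation makes total gamma power *exactly* independent of
the coupling depth, so power effects and coupling effects can be
programmed independently. (Normalising by the envelope peak, `1/(1+m)`,
would reduce gamma power by ~3.4 dB at m = 0.6 and confound the two.)
The recorded ground truth is `20·log₁₀(A_stim/A_base)` per band, exact by
construction.

### Default parameters

| parameter | default | why |
|---|---|---|
| fs_raw / analysis rate | 1000 / 300 Hz | typical acquisition rate; 300 Hz keeps the 34–100 Hz PAC amplitude range below Nyquist |
| trials per subject | 110 (patients) / 117 (controls) | post-artifact-rejection trial counts typical of a 150-trial grating session |
| alpha | f ~ N(8.75, 0.4) Hz, base amplitude 1.0, stimulus change ~ N(group mean, 1.4) dB | alpha sits where group PAC concentrates (8–9 Hz phase); −1.57 / −1.99 dB group means emulate a modest, non-significant desynchronisation difference |
| gamma | f ~ N(55, 3) Hz, base amplitude 0.5, stimulus change ~ N(3.20 or 2.27, 1.26) dB | narrow-band induced gamma in the 40–70 Hz analysis band; group means/SD programme a between-group effect of d ≈ 0.74 |
| coupling depth m | N(0.1, 0.10) patients, N(0.6, 0.15) controls, clipped to [0, 1]; baseline m = 0 | coupling is stimulus-induced; the group difference programmes a large control-greater PAC effect |
| 1/f noise | β = 1, σ = 0.3 | ~8% of baseline gamma-band power, so band metrics are noise-limited but recoverable |
| sensor model | 30 sensors on a spherical cap, 4³ grid, lead field 1/(d²+ε), white sensor noise σ = 20 | enough structure to exercise LCMV unit gain, regularisation and point-source recovery; deliberately no head-geometry physics |

No amplitude/SNR figures exist for the real recordings, so absolute
amplitudes are arbitrary units; all of the above is config-exposed.

### What the generator does not emulate

Evoked (phase-locked) components, eye-blink/cardiac artifacts, channel
dropout, head movement, realistic lead fields, inter-regional
connectivity, or broadband gamma. Passing recovery tests therefore shows
the *estimators and statistics* behave correctly under the assumed signal
model — not that the pipeline is robust to every property of real MEG.

## Pre-processing

Butterworth filters are designed as second-order sections and applied
bidirectionally (`sosfiltfilt`): zero phase, squared magnitude response.
Power-line removal uses sequential ±1 Hz band-stops at 50/100/150 Hz —
narrow, to minimally distort the 34–100 Hz amplitude band. Decimation to
300 Hz applies an explicit zero-phase low-pass at 0.45·300 = 135 Hz
before polyphase resampling: a 250 Hz passband would alias, and 135 Hz
preserves the full PAC amplitude range. Epoch padding (2.5 s each side)
is carried through every filtering and time–frequency step and excluded
only when analysis windows are cut, so edge artifacts never enter any
average. A regression test confirms comodulograms computed at 1000 Hz and
at the decimated 300 Hz rate agree to < 0.05 MVL units.

## Beamformer

The LCMV filter for lead-field column l is `w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹`, unit
gain by construction (asserted to 1e-6 in tests). C is estimated from the
band-limited (40–70 or 8–13 Hz), sample-weighted concatenation of the
baseline and stimulus windows — a *common* filter, so power differences
between windows are not an artifact of different filters — and
regularised as `C + (λ/100)·mean(diag C)·I` with λ = 5%. Window power is
the quadratic form `wᵀC_win w`, equivalent to time-resolved power
averaged over the window and numerically simpler. The ROI ("calcarine"
stand-in: the posterior face of the toy grid) peak is the masked argmax
of the gamma dB map, ties broken to the lowest grid index. The virtual
electrode applies the gamma-band-derived weights to *broadband* sensor
data, matching standard practice for subsequent cross-frequency analysis;
the covariance band is a config switch. Lead fields are fixed-orientation
scalars — orientation handling belongs to real-anatomy machinery, out of
scope here.

## Spectral estimation

Sliding tapered windows projected onto complex exponentials (the
`mtmconvol` construction). Gamma: 0.5 s windows stepped by 0.02 s, DPSS
tapers with time–bandwidth NW = 0.5 s × 7 Hz = 3.5, K = ⌊2NW−1⌋ = 6
tapers, ±7 Hz smoothing, on a 40–70 Hz grid in 2 Hz steps (the native
resolution of a 0.5 s window). Alpha: a single Hanning taper on an
8–13 Hz, 1 Hz grid stepped by 0.1 s. A 0.1 s *window* cannot resolve a
1 Hz grid (≥10 Hz resolution), so the 0.1 s figure is interpreted as the
slide step with a 0.5 s window; both readings are config-exposed. Powers
are one-sided PSDs (unit-energy tapers, 2/fs scaling), averaged over
trials then tapers, validated against Welch estimates on white noise.

Band change is `10·log₁₀(mean P_stim / mean P_base)` over band bins with
stimulus window 0.3–1.5 s and baseline −1.5 to −0.3 s. (Where a 0.3–1.2 s
stimulus window is wanted for the gamma scalar contrast, it is a config
override; the default keeps one window for all metrics.) Peak frequency
is the largest strict local maximum of the per-bin dB-change spectrum
(`find_peaks`), computed on the change rather than the raw stimulus
spectrum so the 1/f background does not dominate; for alpha the spectrum
is negated first, since the response is a trough. A monotone spectrum
returns the band argmax flagged `endpoint_fallback`. On strongly coupled
simulations the gamma dB-change spectrum peaks at the modulation
sidebands (f_γ ± f_α) rather than the carrier — a property of the
generator's strictly sinusoidal carrier, not of the estimator.

## Phase–amplitude coupling

Phase: analytic-signal angle of a ±1 Hz band-pass (matching the 1 Hz
phase grid). Amplitude: analytic-signal modulus of a ±13 Hz band-pass —
the half-bandwidth must be at least the highest phase frequency so the
modulation sidebands at f_amp ± f_phase survive; a comparative test
confirms that a 5 Hz half-bandwidth degrades modulation recovery. The
estimator is the amplitude-corrected MVL (bounded in [0, 1] by
Cauchy–Schwarz, amplitude-scale invariant, zero in expectation for
uniform phase). Analysis windows are cut *after* filtering and Hilbert
transform of the full padded epoch and concatenated across trials, giving
one estimate per bin from the maximal sample count (per-trial averaging
is available). Baseline correction subtracts the comodulogram of the
equally long −1.5 to −0.3 s window, so corrected values may be negative.
The default grid (7 phase × 34 amplitude bins) includes both 34 and
100 Hz endpoints.

## Group statistics

Scalar contrasts use the pooled-variance Student t (the reported df of
n₁+n₂−2 implies pooled, not Welch) with Cohen's d from the same pooled
SD; `t = d·√(n₁n₂/(n₁+n₂))` holds to 1e-12 for every computed result and
doubles as a consistency check on reported values. The comodulogram
comparison thresholds per-bin t at the two-tailed 5% critical value,
forms clusters under 4-connectivity (conservative rectangular-grid
semantics; 8-connectivity available) separately per sign, and carries
forward the maximum |t| within each cluster (sum-of-t is the field's
common default and available by switch, but max-|t| is this pipeline's
definition). The null distribution records the largest per-tail cluster
statistic over relabelings of group membership; tails are kept separate
and tested at α = 0.025 each. Random-relabeling p-values use the +1
finite-sample correction; an exact enumeration mode covers all distinct
relabelings and is verified against a brute-force oracle at n₁ = n₂ = 3.
The empirical type-I rate (any significant cluster under identical
generators) is checked to sit within binomial bounds of 5%; the max-|t|
statistic runs somewhat conservative, which is the expected direction.

## Problem sizes used in validation

Recovery suites use 100-trial subjects simulated directly at 300 Hz (20
seeds for coupling-bin recovery, 10 for gamma dB, 20 for beamformer
localisation at 0 dB sensor SNR); the type-I check uses 30 cohorts of
18/16 comodulograms at 1000 relabelings; the end-to-end replication
experiment uses the full 18/16 design with 40 trials per subject and 1000
relabelings. These sizes are the package's validation defaults — large
enough for the stated tolerances (±0.5 dB, ≥18/20 and ≥19/20 hit rates,
binomial bounds) while keeping a full validation run in the minutes
range; the scientific defaults of the generator itself (110/117 trials,
10 000 relabelings) are unchanged.

## Known limitations

* The toy lead field has no null space structure of real MEG; depth bias
  and correlated-source suppression are not exercised.
* PAC significance is assessed only via the group-level cluster test;
  within-subject surrogate testing is not implemented.
* Theta–gamma coupling is out of scope (epochs are too short for reliable
  theta phase estimation), as are alternative PAC estimators (modulation
  index, GLM-based PAC).
* The comodulogram concatenates trials; subjects with very different
  trial counts weight bins accordingly.
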