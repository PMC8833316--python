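# megpac

Beamformed MEG analysis of visual-cortex oscillations — induced gamma and
alpha power, alpha–gamma phase–amplitude coupling (PAC), and group-level
cluster statistics — packaged with a cohort simulator that provides fully
known ground truth.

## Who this is for

Studies of cortical dysrhythmia (visual snow syndrome, tinnitus, and other
disorders of phantom perception) compare stimulus-induced oscillations
between a patient and a control group: a visual grating elicits a
narrow-band gamma (40–70 Hz) power increase and an alpha (8–13 Hz) power
decrease in primary visual cortex, and the amplitude of gamma is normally
modulated by the phase of alpha. Because patient MEG recordings usually
cannot be shared, the statistical pipeline itself must be validated on
synthetic cohorts whose effects are programmed in. `megpac` provides both
halves: the analysis chain and the generator.

## What it computes

* **Simulation** (`megpac.synth`): trial-epoched recordings with a 1/f
  background, an ongoing alpha rhythm that desynchronises after stimulus
  onset, induced narrow-band gamma, and alpha-phase → gamma-amplitude
  coupling of depth *m* ∈ [0, 1] via an RMS-normalised envelope
  `(1 + m·cos(φ_α − φ_pref)) / √(1 + m²/2)`, so gamma power is independent
  of *m*. Two-group cohorts (default 18 patients / 16 controls) draw
  per-subject effects from configurable group distributions.
* **Pre-processing** (`megpac.preprocess`): fourth-order bidirectional
  Butterworth band-pass (0.5–250 Hz), power-line notches (50 Hz and
  harmonics), stimulus-locked epoching with 2.5 s edge padding, polyphase
  decimation to 300 Hz.
* **Beamforming** (`megpac.beamformer`): LCMV spatial filters
  `w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹` with 5% diagonal loading, band-limited common
  covariance over baseline + stimulus windows, per-grid dB change maps,
  ROI peak selection, and broadband virtual-electrode extraction.
* **Spectral metrics** (`megpac.spectral`): multitaper (DPSS, ±7 Hz
  smoothing) and Hanning sliding-window power, band changes in dB
  (`10·log₁₀(P_stim/P_base)`, 0.3–1.5 s vs −1.5 to −0.3 s), peak
  frequency, baseline power.
* **PAC** (`megpac.pac`): amplitude-corrected mean vector length

  `MVL = |Σₜ aₜ e^{iφₜ}| / (√N · √(Σₜ aₜ²))  ∈ [0, 1]`

  over a 7–13 Hz × 34–100 Hz comodulogram, baseline-corrected by
  subtraction.
* **Statistics** (`megpac.stats`): pooled-variance two-sample t with
  Cohen's d (`t = d·√(n₁n₂/(n₁+n₂))`), and a two-dimensional
  cluster-based permutation test (per-bin t thresholded at two-tailed 5%,
  max-|t| cluster statistic, 10 000 group relabelings, 0.025 per tail).
* **Orchestration** (`megpac.pipeline`, `megpac.io`, `megpac` CLI): HDF5
  epoch container, YAML configuration, and an end-to-end replication
  experiment writing CSV/JSON bundles stamped with config hash and seed.

## Worked example

```python
import numpy as np
from megpac import (SubjectSimConfig, VirtualElectrode, simulate_subject,
                    decimate, multitaper_tfr, band_power_change, peak_frequency,
                    corrected_comodulogram)

cfg = SubjectSimConfig(n_trials=60, seed=42, coupling_m=0.8,
                       alpha_freq=10.0, gamma_freq=55.0)
ep = simulate_subject(cfg)                 # 60 padded epochs at 1000 Hz
ve = VirtualElectrode.from_epochs(decimate(ep, 300.0))

tfr = multitaper_tfr(ve)                   # 40-70 Hz, 0.5 s window, 6 DPSS tapers
change = band_power_change(tfr, (40.0, 70.0))
comod = corrected_comodulogram(ve)         # PAC(0.3-1.5 s) - PAC(baseline)

print(f"programmed gamma change: {cfg.gamma_change_db:+.2f} dB")
print(f"recovered gamma change:  {change.change_db:+.2f} dB")
fp, fa = comod.peak_bin()
print(f"PAC peak: phase {fp:.0f} Hz x amplitude {fa:.0f} Hz "
      f"(programmed 10 x 55), value {comod.values.max():.3f}")
```

prints

```
programmed gamma change: +3.01 dB
recovered gamma change:  +2.80 dB
PAC peak: phase 10 Hz x amplitude 56 Hz (programmed 10 x 55), value 0.307
```

The recovered band change sits ~0.2 dB below the programmed value because
the 1/f background contributes equally to both analysis windows; the
corrected comodulogram finds the programmed coupling bin (the amplitude
grid has 2 Hz steps, so 55 Hz lands on the 54/56 Hz bins).

The whole experiment — cohort simulation through group statistics — runs
from the command line:

```bash
megpac run-all --out results/        # defaults: 18 patients vs 16 controls
megpac simulate --config cfg.yaml --out sim/   # or stage by stage:
megpac preprocess --in sim/patient-00.h5 --out pre.h5
megpac beamform --in pre.h5 --out ve.h5 --band 40 70
megpac power --in ve.h5 --band gamma
megpac pac --in ve.h5 --out pac/
megpac compare --a pac_patients/ --b pac_controls/ --n-perm 10000 --seed 1
```

`run-all` writes `subject_metrics.csv` (per-subject band changes, peak
frequencies, baseline power, ground truth), `pac_clusters.json`
(versioned cluster schema) and `summary.json` (group tests, significant
clusters, effect sizes, config hash, master seed). Re-running with the
same master seed reproduces the bundle byte for byte.

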