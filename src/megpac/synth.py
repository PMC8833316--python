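"""Ground-truth cohort simulator.

Generates trial-epoched virtual-electrode (and, via a toy lead field,
sensor-level) recordings with the statistical structure the analysis
pipeline assumes: a 1/f background, an ongoing alpha rhythm (~10 Hz) that
desynchronises after stimulus onset, a stimulus-induced narrow-band gamma
oscillation (40-70 Hz), and alpha-phase -> gamma-amplitude coupling of
controllable depth.  Every programmed effect is recorded in the epoch
metadata so estimator recovery can be checked against known truth.

The coupling acts multiplicatively on the gamma envelope,

    g(t) = A_gamma * (1 + m * cos(phi_alpha(t) - phi_pref)) / sqrt(1 + m^2/2),

with modulation depth ``m`` in [0, 1].  Since the mean square of
(1 + m*cos) over alpha cycles is 1 + m^2/2, the RMS normalisation makes
total gamma power exactly invariant to ``m``, letting power and coupling
effects be manipulated independently.
Carrier phase offsets are redrawn per trial, so the gamma response is
induced (power appears in trial-averaged spectra) rather than evoked
(it cancels in the trial-averaged waveform).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .containers import EpochSet
from .beamformer import SourceModel

__all__ = [
    "SubjectSimConfig",
    "GroupSpec",
    "CohortSpec",
    "one_over_f_noise",
    "make_pac_signal",
    "simulate_subject",
    "draw_cohort_configs",
    "simulate_cohort",
    "project_to_sensors",
]


@dataclass
class SubjectSimConfig:
    """Generative parameters for one simulated subject.

    Amplitudes are in arbitrary units; dB changes recorded as ground truth
    are 20*log10 of the stimulus/baseline amplitude ratio.
    """

    fs_raw: float = 1000.0
    n_trials: int = 110
    epoch_pre_s: float = 1.5
    epoch_post_s: float = 1.5
    pad_s: float = 2.5
    alpha_freq: float = 10.0
    alpha_amp_base: float = 1.0
    alpha_amp_stim: float = 0.7943282347242815  # -2 dB re baseline
    gamma_freq: float = 55.0
    gamma_amp_base: float = 0.5
    gamma_amp_stim: float = 0.7071067811865476  # +3.0103 dB re baseline
    coupling_m: float = 0.6          # modulation depth during stimulus
    coupling_m_base: float = 0.0     # modulation depth during baseline
    coupling_phase_pref: float = 0.0  # radians, alpha phase of max gamma envelope
    noise_exponent: float = 1.0      # 1/f^beta PSD slope
    noise_amp: float = 0.3           # noise standard deviation
    seed: int = 0

    def validate(self) -> None:
        amps = (self.alpha_amp_base, self.alpha_amp_stim,
                self.gamma_amp_base, self.gamma_amp_stim, self.noise_amp)
        vals = amps + (self.fs_raw, self.alpha_freq, self.gamma_freq,
                       self.coupling_m, self.coupling_m_base,
                       self.coupling_phase_pref, self.noise_exponent,
                       self.epoch_pre_s, self.epoch_post_s, self.pad_s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite value in SubjectSimConfig")
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        for m in (self.coupling_m, self.coupling_m_base):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"coupling depth must lie in [0, 1], got {m}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.epoch_pre_s <= 0 or self.epoch_post_s <= 0:
            raise ValueError("epoch windows must be positive")
        if self.fs_raw <= 0:
            raise ValueError("fs_raw must be positive")

    @staticmethod
    def _amp_ratio_db(stim: float, base: float) -> float:
        if base == 0.0:
            return 0.0 if stim == 0.0 else float("inf")
        return 20.0 * float(np.log10(stim / base))

    @property
    def gamma_change_db(self) -> float:
        """Programmed gamma power change, 20*log10(amplitude ratio)."""
        return self._amp_ratio_db(self.gamma_amp_stim, self.gamma_amp_base)

    @property
    def alpha_change_db(self) -> float:
        return self._amp_ratio_db(self.alpha_amp_stim, self.alpha_amp_base)


@dataclass
class GroupSpec:
    """Between-subject distribution of generative parameters for one group."""

    name: str
    n_subjects: int
    base: SubjectSimConfig
    gamma_change_db_mean: float = 3.20
    gamma_change_db_sd: float = 1.26
    alpha_change_db_mean: float = -2.0
    alpha_change_db_sd: float = 1.4
    coupling_m_mean: float = 0.6
    coupling_m_sd: float = 0.15
    alpha_freq_mean: float = 8.75
    alpha_freq_sd: float = 0.4
    gamma_freq_mean: float = 55.0
    gamma_freq_sd: float = 3.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("group sizes must be >= 2")
        for sd in (self.gamma_change_db_sd, self.alpha_change_db_sd, self.coupling_m_sd,
                   self.alpha_freq_sd, self.gamma_freq_sd):
            if sd < 0:
                raise ValueError("between-subject SDs must be >= 0")
        self.base.validate()


def _default_patients() -> GroupSpec:
    return GroupSpec(
        name="patient", n_subjects=18,
        base=SubjectSimConfig(n_trials=110),
        gamma_change_db_mean=3.20, gamma_change_db_sd=1.26,
        alpha_change_db_mean=-1.57, alpha_change_db_sd=1.4,
        coupling_m_mean=0.1, coupling_m_sd=0.10,
    )


def _default_controls() -> GroupSpec:
    return GroupSpec(
        name="control", n_subjects=16,
        base=SubjectSimConfig(n_trials=117),
        gamma_change_db_mean=2.27, gamma_change_db_sd=1.26,
        alpha_change_db_mean=-1.99, alpha_change_db_sd=1.4,
        coupling_m_mean=0.6, coupling_m_sd=0.15,
    )


@dataclass
class CohortSpec:
    """Two-group cohort design.

    Defaults emulate a patient/control MEG study: 18 patients with a
    larger induced-gamma increase but weak alpha-gamma coupling, and 16
    controls with a smaller gamma increase but strong coupling.
    """

    group_a: GroupSpec = field(default_factory=_default_patients)
    group_b: GroupSpec = field(default_factory=_default_controls)
    master_seed: int = 0

    def validate(self) -> None:
        self.group_a.validate()
        self.group_b.validate()


def one_over_f_noise(exponent: float, duration_s: float, fs: float,
                     seed: int | np.random.Generator = 0,
                     n_samples: int | None = None) -> np.ndarray:
    """Zero-mean, unit-variance noise with a 1/f**exponent power spectrum.

    Spectral shaping in the frequency domain: Gaussian white noise is
    scaled by f**(-exponent/2) (DC removed) and transformed back.

    Parameters
    ----------
    exponent : float
        PSD slope beta >= 0; 0 gives white noise.
    duration_s, fs : float
        Length and sampling rate; ``n_samples`` overrides duration_s.
    seed : int or numpy Generator
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs)) if n_samples is None else int(n_samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _pac_trace(t: np.ndarray, alpha_freq: float, gamma_freq: float,
               alpha_amp: np.ndarray, gamma_amp: np.ndarray, m: np.ndarray,
               phase_pref: float, phi0: float, psi0: float) -> np.ndarray:
    """Deterministic (noise-free) alpha + coupled-gamma trace.

    ``alpha_amp``, ``gamma_amp`` and ``m`` may vary over time (piecewise
    baseline/stimulus profiles); carrier phases stay continuous.
    """
    phi_alpha = 2.0 * np.pi * alpha_freq * t + phi0
    alpha = alpha_amp * np.cos(phi_alpha)
    env = gamma_amp * (1.0 + m * np.cos(phi_alpha - phase_pref)) / np.sqrt(1.0 + m ** 2 / 2.0)
    gamma = env * np.cos(2.0 * np.pi * gamma_freq * t + psi0)
    return alpha + gamma


def make_pac_signal(cfg: SubjectSimConfig, duration_s: float, stim_on: bool,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Single-trial stationary signal under baseline or stimulus conditions.

    Returns ``alpha + coupled gamma + 1/f noise`` sampled at ``cfg.fs_raw``.
    ``stim_on`` selects the stimulus amplitudes and coupling depth;
    otherwise baseline values are used.  Carrier phase offsets are drawn
    from the provided generator (or one seeded from ``cfg.seed``).
    """
    cfg.validate()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.fs_raw))
    t = np.arange(n) / cfg.fs_raw
    phi0, psi0 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    if stim_on:
        a_amp, g_amp, m = cfg.alpha_amp_stim, cfg.gamma_amp_stim, cfg.coupling_m
    else:
        a_amp, g_amp, m = cfg.alpha_amp_base, cfg.gamma_amp_base, cfg.coupling_m_base
    x = _pac_trace(t, cfg.alpha_freq, cfg.gamma_freq,
                   np.full(n, a_amp), np.full(n, g_amp), np.full(n, m),
                   cfg.coupling_phase_pref, phi0, psi0)
    if cfg.noise_amp > 0:
        x = x + cfg.noise_amp * one_over_f_noise(
            cfg.noise_exponent, duration_s, cfg.fs_raw, seed=rng, n_samples=n)
    return x


def simulate_subject(cfg: SubjectSimConfig) -> EpochSet:
    """Simulate one subject's trial-epoched virtual-electrode recording.

    Each epoch spans [-(pre+pad), +(post+pad)] s around stimulus onset at
    ``cfg.fs_raw``.  Pre-onset samples use baseline amplitudes/coupling,
    post-onset samples the stimulus values; carrier phase is continuous
    across the onset.  Programmed dB changes and coupling depths are
    recorded in ``meta``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_pre = int(round((cfg.epoch_pre_s + cfg.pad_s) * cfg.fs_raw))
    n_post = int(round((cfg.epoch_post_s + cfg.pad_s) * cfg.fs_raw))
    n = n_pre + n_post
    times = (np.arange(n) - n_pre) / cfg.fs_raw
    stim = times >= 0
    alpha_amp = np.where(stim, cfg.alpha_amp_stim, cfg.alpha_amp_base)
    gamma_amp = np.where(stim, cfg.gamma_amp_stim, cfg.gamma_amp_base)
    m = np.where(stim, cfg.coupling_m, cfg.coupling_m_base)

    data = np.empty((cfg.n_trials, 1, n))
    for k in range(cfg.n_trials):
        phi0, psi0 = rng.uniform(0.0, 2.0 * np.pi, size=2)
        x = _pac_trace(times, cfg.alpha_freq, cfg.gamma_freq,
                       alpha_amp, gamma_amp, m,
                       cfg.coupling_phase_pref, phi0, psi0)
        if cfg.noise_amp > 0:
            x = x + cfg.noise_amp * one_over_f_noise(
                cfg.noise_exponent, 0.0, cfg.fs_raw, seed=rng, n_samples=n)
        data[k, 0] = x

    meta = {
        "gamma_change_db": cfg.gamma_change_db,
        "alpha_change_db": cfg.alpha_change_db,
        "coupling_m": cfg.coupling_m,
        "coupling_m_base": cfg.coupling_m_base,
        "alpha_freq": cfg.alpha_freq,
        "gamma_freq": cfg.gamma_freq,
        "sim_config": asdict(cfg),
    }
    return EpochSet(data=data, fs=cfg.fs_raw, times=times,
                    subject_id=f"sim-{cfg.seed}", group="", pad_s=cfg.pad_s,
                    meta=meta)


def _draw_subject_cfg(spec: GroupSpec, rng: np.random.Generator,
                      seed: int) -> SubjectSimConfig:
    g_db = rng.normal(spec.gamma_change_db_mean, spec.gamma_change_db_sd)
    a_db = rng.normal(spec.alpha_change_db_mean, spec.alpha_change_db_sd)
    m = float(np.clip(rng.normal(spec.coupling_m_mean, spec.coupling_m_sd), 0.0, 1.0))
    alpha_f = max(1.0, rng.normal(spec.alpha_freq_mean, spec.alpha_freq_sd))
    gamma_f = max(20.0, rng.normal(spec.gamma_freq_mean, spec.gamma_freq_sd))
    base = spec.base
    return replace(
        base,
        gamma_amp_stim=base.gamma_amp_base * 10.0 ** (g_db / 20.0),
        alpha_amp_stim=base.alpha_amp_base * 10.0 ** (a_db / 20.0),
        coupling_m=m,
        alpha_freq=float(alpha_f),
        gamma_freq=float(gamma_f),
        seed=seed,
    )


def draw_cohort_configs(spec: CohortSpec) -> list[tuple[str, SubjectSimConfig]]:
    """Draw per-subject generative parameters for a cohort (no signals yet).

    Returns (group name, config) pairs; reproducible from ``master_seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.master_seed)
    n_total = spec.group_a.n_subjects + spec.group_b.n_subjects
    child_seeds = ss.generate_state(n_total + 1)
    draw_rng = np.random.default_rng(child_seeds[0])
    out: list[tuple[str, SubjectSimConfig]] = []
    idx = 1
    for grp in (spec.group_a, spec.group_b):
        for _ in range(grp.n_subjects):
            sub_seed = int(child_seeds[idx] % (2 ** 31))
            out.append((grp.name, _draw_subject_cfg(grp, draw_rng, sub_seed)))
            idx += 1
    return out


def simulate_cohort(spec: CohortSpec) -> list[EpochSet]:
    """Simulate a labelled two-group cohort.

    Per-subject parameters are drawn from the group distributions using a
    seed sequence spawned from ``master_seed``, so the whole cohort is
    reproducible from that one integer.
    """
    subjects: list[EpochSet] = []
    counters: dict[str, int] = {}
    for group, cfg in draw_cohort_configs(spec):
        ep = simulate_subject(cfg)
        j = counters.get(group, 0)
        counters[group] = j + 1
        ep.group = group
        ep.subject_id = f"{group}-{j:02d}"
        subjects.append(ep)
    return subjects


def project_to_sensors(source_epochs: EpochSet, model: SourceModel,
                       source_index: int, sensor_noise_amp: float = 0.0,
                       seed: int | np.random.Generator = 0) -> EpochSet:
    """Forward-project a single-channel source onto the toy sensor array.

    sensor data = leadfield column x source series + independent white
    sensor noise (per trial, channel and sample).
    """
    if not 0 <= source_index < model.n_grid:
        raise ValueError(f"source_index {source_index} outside grid of {model.n_grid}")
    if source_epochs.n_channels != 1:
        raise ValueError("source_epochs must have exactly one channel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = model.leadfield[:, source_index]  # (n_sensors,)
    src = source_epochs.data[:, 0, :]       # (n_trials, n_samples)
    data = col[None, :, None] * src[:, None, :]
    if sensor_noise_amp > 0:
        data = data + sensor_noise_amp * rng.standard_normal(data.shape)
    out = source_epochs.copy_with(data=data)
    out.meta["true_source_index"] = int(source_index)
    return out
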