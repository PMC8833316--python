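"""Alpha-gamma phase-amplitude coupling (PAC).

The estimator is the amplitude-corrected mean vector length (MVL): with
low-frequency phase phi_t and high-frequency envelope a_t over N samples,

    MVL = (1/sqrt(N)) * |sum_t a_t exp(i phi_t)| / sqrt(sum_t a_t^2),

which lies in [0, 1] by Cauchy-Schwarz and is invariant to amplitude
scaling.  Phase comes from the analytic signal of a narrow band-pass
(f_phase +- 1 Hz by default); the envelope band-pass must be wide enough
to admit the modulation sidebands, so its half-bandwidth defaults to
13 Hz (>= the highest phase frequency on the grid).

Comodulograms evaluate MVL on a (phase frequency x amplitude frequency)
grid, concatenating the analysis window across trials so each bin gets a
single estimate from the maximal number of samples.  Baseline correction
subtracts the comodulogram of an equally long pre-stimulus window, so
corrected values may be negative.  Filtering and Hilbert transforms run
over the full padded epoch; padding is discarded only when the analysis
windows are cut, keeping filter edge artefacts out of every estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .containers import VirtualElectrode
from .preprocess import FilterSpec, butter_filter

__all__ = [
    "Comodulogram",
    "extract_phase",
    "extract_amplitude",
    "mvl_ozkurt",
    "comodulogram",
    "corrected_comodulogram",
    "DEFAULT_PHASE_FREQS",
    "DEFAULT_AMP_FREQS",
]

DEFAULT_PHASE_FREQS = np.arange(7.0, 13.0 + 1e-9, 1.0)    # 7 bins
DEFAULT_AMP_FREQS = np.arange(34.0, 100.0 + 1e-9, 2.0)    # 34 bins


@dataclass
class Comodulogram:
    """PAC values over a (phase freq x amplitude freq) grid."""

    values: np.ndarray        # (n_phase, n_amp)
    phase_freqs: np.ndarray   # Hz
    amp_freqs: np.ndarray     # Hz
    window: tuple[float, float]
    corrected: bool
    subject_id: str = ""
    group: str = ""
    meta: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.phase_freqs = np.asarray(self.phase_freqs, float)
        self.amp_freqs = np.asarray(self.amp_freqs, float)
        if self.values.shape != (len(self.phase_freqs), len(self.amp_freqs)):
            raise ValueError("values shape does not match frequency grids")
        lo, hi = (-1.0, 1.0) if self.corrected else (0.0, 1.0)
        if np.any(self.values < lo - 1e-9) or np.any(self.values > hi + 1e-9):
            raise ValueError(f"values outside [{lo}, {hi}] for corrected={self.corrected}")

    def peak_bin(self) -> tuple[float, float]:
        """(phase_freq, amp_freq) of the matrix maximum."""
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


def _analytic(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    return signal.hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]


def extract_phase(ve: VirtualElectrode, f_phase: float,
                  half_bw: float = 1.0, order: int = 4) -> np.ndarray:
    """Per-trial instantaneous phase (radians) of the f_phase +- half_bw band.

    Cosine convention: phase 0 at the band-limited signal's peaks.
    """
    spec = FilterSpec("bandpass", f_phase - half_bw, f_phase + half_bw, order=order)
    filtered = butter_filter(ve.data, ve.fs, spec)
    return np.angle(_analytic(filtered))


def extract_amplitude(ve: VirtualElectrode, f_amp: float,
                      half_bw: float = 13.0, order: int = 4) -> np.ndarray:
    """Per-trial envelope of the f_amp +- half_bw band (analytic modulus).

    ``half_bw`` should be at least the highest phase frequency of
    interest so the modulation sidebands at f_amp +- f_phase survive the
    filter.
    """
    if f_amp + half_bw >= ve.fs / 2.0:
        raise ValueError(
            f"amplitude band {f_amp}+-{half_bw} Hz exceeds Nyquist {ve.fs / 2.0} Hz")
    spec = FilterSpec("bandpass", f_amp - half_bw, f_amp + half_bw, order=order)
    filtered = butter_filter(ve.data, ve.fs, spec)
    return np.abs(_analytic(filtered))


def mvl_ozkurt(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Amplitude-corrected mean vector length of one phase/amplitude pair."""
    phase = np.ravel(phase)
    amplitude = np.ravel(amplitude)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    n = phase.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    energy = float(amplitude @ amplitude)
    if energy == 0.0:
        raise ValueError("amplitude is identically zero")
    num = np.abs(np.sum(amplitude * np.exp(1j * phase)))
    return float(num / (np.sqrt(n) * np.sqrt(energy)))


def _mvl_matrix(phases: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """MVL for every (phase row x amplitude row) pair.

    phases : (n_phase, N); amps : (n_amp, N) -> (n_phase, n_amp)
    """
    n = phases.shape[1]
    unit = np.exp(1j * phases)
    sums = unit @ amps.T                      # (n_phase, n_amp) complex
    energy = np.einsum("an,an->a", amps, amps)  # (n_amp,)
    return np.abs(sums) / (np.sqrt(n) * np.sqrt(energy)[None, :])


def _windowed_series(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Cut (trials, samples) to the window and concatenate trials."""
    return series[:, mask].reshape(-1)


def comodulogram(ve: VirtualElectrode, window: tuple[float, float] = (0.3, 1.5),
                 phase_freqs: np.ndarray | None = None,
                 amp_freqs: np.ndarray | None = None,
                 phase_half_bw: float = 1.0, amp_half_bw: float = 13.0) -> Comodulogram:
    """Uncorrected PAC comodulogram over the analysis window."""
    out = _comodulograms(ve, [window], phase_freqs, amp_freqs,
                         phase_half_bw, amp_half_bw)
    values = out[0]
    pf = DEFAULT_PHASE_FREQS if phase_freqs is None else np.asarray(phase_freqs, float)
    af = DEFAULT_AMP_FREQS if amp_freqs is None else np.asarray(amp_freqs, float)
    return Comodulogram(values=values, phase_freqs=pf, amp_freqs=af,
                        window=tuple(window), corrected=False,
                        subject_id=ve.subject_id, group=ve.group, meta=dict(ve.meta))


def _comodulograms(ve: VirtualElectrode, windows: list[tuple[float, float]],
                   phase_freqs: np.ndarray | None, amp_freqs: np.ndarray | None,
                   phase_half_bw: float, amp_half_bw: float) -> list[np.ndarray]:
    """Shared filtering pass: one comodulogram matrix per requested window."""
    pf = DEFAULT_PHASE_FREQS if phase_freqs is None else np.asarray(phase_freqs, float)
    af = DEFAULT_AMP_FREQS if amp_freqs is None else np.asarray(amp_freqs, float)
    masks = []
    for w in windows:
        m = ve.time_mask(*w)
        if not m.any():
            raise ValueError(f"window {w} not covered by epoch times")
        masks.append(m)
    phase_rows = [np.stack([_windowed_series(ph, m) for m in masks])
                  for ph in (extract_phase(ve, f, half_bw=phase_half_bw) for f in pf)]
    amp_rows = [np.stack([_windowed_series(am, m) for m in masks])
                for am in (extract_amplitude(ve, f, half_bw=amp_half_bw) for f in af)]
    out = []
    for wi in range(len(windows)):
        ph_mat = np.stack([r[wi] for r in phase_rows])
        am_mat = np.stack([r[wi] for r in amp_rows])
        out.append(_mvl_matrix(ph_mat, am_mat))
    return out


def corrected_comodulogram(ve: VirtualElectrode,
                           stim_win: tuple[float, float] = (0.3, 1.5),
                           base_win: tuple[float, float] = (-1.5, -0.3),
                           phase_freqs: np.ndarray | None = None,
                           amp_freqs: np.ndarray | None = None,
                           phase_half_bw: float = 1.0,
                           amp_half_bw: float = 13.0) -> Comodulogram:
    """Baseline-corrected comodulogram: PAC(stimulus) - PAC(baseline).

    Both windows must have equal duration so the two MVL estimates share
    the same sampling variability.
    """
    dur_s = stim_win[1] - stim_win[0]
    dur_b = base_win[1] - base_win[0]
    if not np.isclose(dur_s, dur_b):
        raise ValueError(
            f"stimulus window ({dur_s} s) and baseline window ({dur_b} s) "
            "must have equal duration")
    stim, base = _comodulograms(ve, [stim_win, base_win], phase_freqs, amp_freqs,
                                phase_half_bw, amp_half_bw)
    pf = DEFAULT_PHASE_FREQS if phase_freqs is None else np.asarray(phase_freqs, float)
    af = DEFAULT_AMP_FREQS if amp_freqs is None else np.asarray(amp_freqs, float)
    return Comodulogram(values=stim - base, phase_freqs=pf, amp_freqs=af,
                        window=tuple(stim_win), corrected=True,
                        subject_id=ve.subject_id, group=ve.group, meta=dict(ve.meta))
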