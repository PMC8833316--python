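"""Time-frequency power on virtual electrodes and derived band metrics.

Power is estimated with sliding tapered windows (Fieldtrip ``mtmconvol``
style): at each window position and target frequency the data segment is
projected onto taper * complex exponential kernels and taper-averaged
power is accumulated.  The gamma band uses multitaper (DPSS) estimation
with +-7 Hz smoothing (time-bandwidth NW = 3.5, K = 6 tapers for the
0.5 s window); the alpha band uses a single Hanning taper on a 1 Hz grid.
Estimates are one-sided PSDs (unit-energy tapers, 2/fs scaling), averaged
across trials so induced (non-phase-locked) power is retained.

Band changes are expressed in dB re the pre-stimulus baseline,
10*log10(P_stim / P_base), matching the convention for induced responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .containers import VirtualElectrode

__all__ = [
    "TimeFreqPower",
    "BandChange",
    "PeakFrequency",
    "multitaper_tfr",
    "hanning_tfr",
    "band_power_change",
    "peak_frequency",
    "baseline_band_power",
]

GAMMA_BAND = (40.0, 70.0)
ALPHA_BAND = (8.0, 13.0)
STIM_WIN = (0.3, 1.5)
BASE_WIN = (-1.5, -0.3)


@dataclass
class TimeFreqPower:
    """Trial-averaged time-frequency power (one-sided PSD units)."""

    power: np.ndarray   # (n_freqs, n_times)
    freqs: np.ndarray   # Hz
    times: np.ndarray   # s, window centres relative to onset
    taper_info: dict[str, Any]
    subject_id: str = ""
    group: str = ""
    meta: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.times >= t_start - 1e-12) & (self.times < t_end - 1e-12)

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0] - 1e-9) & (self.freqs <= band[1] + 1e-9)


@dataclass
class BandChange:
    """Baseline-normalised band power change for one subject."""

    subject_id: str
    group: str
    band: tuple[float, float]
    change_db: float
    stim_win: tuple[float, float]
    base_win: tuple[float, float]


@dataclass
class PeakFrequency:
    """Peak of the dB-change spectrum; flagged when no interior peak exists."""

    freq_hz: float
    endpoint_fallback: bool


def _sliding_taper_power(data: np.ndarray, fs: float, times: np.ndarray,
                         freqs: np.ndarray, win_s: float, step_s: float,
                         tapers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged sliding-window tapered power.

    data : (n_trials, n_samples); tapers : (K, win_n), each unit energy.
    Returns (power (n_freqs, n_pos), centre times (n_pos,)).
    """
    n_trials, n_samples = data.shape
    win_n = tapers.shape[1]
    step_n = max(1, int(round(step_s * fs)))
    if win_n > n_samples:
        raise ValueError(f"window of {win_n} samples exceeds epoch of {n_samples}")
    segs = np.lib.stride_tricks.sliding_window_view(data, win_n, axis=-1)[:, ::step_n, :]
    n_pos = segs.shape[1]
    starts = np.arange(n_pos) * step_n
    centres = times[starts + win_n // 2]
    t_win = np.arange(win_n) / fs
    # kernels (n_freqs * K, win_n): taper-windowed complex exponentials
    arg = 2.0 * np.pi * freqs[:, None] * t_win[None, :]
    kr = np.cos(arg)[:, None, :] * tapers[None, :, :]
    ki = -np.sin(arg)[:, None, :] * tapers[None, :, :]
    kr = kr.reshape(len(freqs) * len(tapers), win_n)
    ki = ki.reshape(len(freqs) * len(tapers), win_n)
    flat = segs.reshape(n_trials * n_pos, win_n)
    cr = flat @ kr.T
    ci = flat @ ki.T
    pw = (cr * cr + ci * ci) * (2.0 / fs)  # one-sided PSD per taper
    pw = pw.reshape(n_trials, n_pos, len(freqs), len(tapers))
    power = pw.mean(axis=(0, 3)).T  # average trials and tapers -> (F, n_pos)
    return power, centres


def multitaper_tfr(ve: VirtualElectrode, freqs: np.ndarray | None = None,
                   win_s: float = 0.5, step_s: float = 0.02,
                   smooth_hz: float = 7.0) -> TimeFreqPower:
    """DPSS multitaper sliding-window power (gamma-band defaults).

    Time-bandwidth product NW = win_s * smooth_hz (default 3.5) with
    K = floor(2 NW - 1) tapers (default 6), giving +-smooth_hz spectral
    smoothing around each target frequency.
    """
    if freqs is None:
        freqs = np.arange(GAMMA_BAND[0], GAMMA_BAND[1] + 1e-9, 2.0)
    freqs = np.asarray(freqs, float)
    nw = win_s * smooth_hz
    if nw < 1:
        raise ValueError(f"time-bandwidth product {nw} < 1; increase win_s or smooth_hz")
    n_tapers = int(np.floor(2 * nw - 1))
    win_n = int(round(win_s * ve.fs))
    tapers = dpss(win_n, nw, Kmax=n_tapers)
    tapers = tapers / np.sqrt((tapers ** 2).sum(axis=1, keepdims=True))
    power, centres = _sliding_taper_power(ve.data, ve.fs, ve.times, freqs,
                                          win_s, step_s, tapers)
    info = {"method": "multitaper", "win_s": win_s, "step_s": step_s,
            "smooth_hz": smooth_hz, "nw": nw, "n_tapers": n_tapers}
    return TimeFreqPower(power=power, freqs=freqs, times=centres, taper_info=info,
                         subject_id=ve.subject_id, group=ve.group, meta=dict(ve.meta))


def hanning_tfr(ve: VirtualElectrode, freqs: np.ndarray | None = None,
                win_s: float = 0.5, step_s: float = 0.1) -> TimeFreqPower:
    """Single Hanning-taper sliding-window power (alpha-band defaults).

    Note the window must be long enough to resolve the 1 Hz frequency
    grid; the default 0.5 s window slides in 0.1 s steps.
    """
    if freqs is None:
        freqs = np.arange(ALPHA_BAND[0], ALPHA_BAND[1] + 1e-9, 1.0)
    freqs = np.asarray(freqs, float)
    win_n = int(round(win_s * ve.fs))
    taper = signal.windows.hann(win_n, sym=False)
    taper = taper / np.sqrt((taper ** 2).sum())
    power, centres = _sliding_taper_power(ve.data, ve.fs, ve.times, freqs,
                                          win_s, step_s, taper[None, :])
    info = {"method": "hanning", "win_s": win_s, "step_s": step_s}
    return TimeFreqPower(power=power, freqs=freqs, times=centres, taper_info=info,
                         subject_id=ve.subject_id, group=ve.group, meta=dict(ve.meta))


def band_power_change(tfr: TimeFreqPower, band: tuple[float, float],
                      stim_win: tuple[float, float] = STIM_WIN,
                      base_win: tuple[float, float] = BASE_WIN) -> BandChange:
    """Stimulus-vs-baseline band power change in dB."""
    fmask = tfr.band_mask(band)
    if not fmask.any():
        raise ValueError(f"band {band} has no frequency bins")
    smask, bmask = tfr.time_mask(*stim_win), tfr.time_mask(*base_win)
    if not smask.any() or not bmask.any():
        raise ValueError("stimulus or baseline window not covered by TFR times")
    p_stim = tfr.power[np.ix_(fmask, smask)].mean()
    p_base = tfr.power[np.ix_(fmask, bmask)].mean()
    if p_base <= 0:
        raise ValueError("baseline power is zero; dB change undefined")
    change = 10.0 * np.log10(p_stim / p_base)
    return BandChange(subject_id=tfr.subject_id, group=tfr.group,
                      band=tuple(band), change_db=float(change),
                      stim_win=tuple(stim_win), base_win=tuple(base_win))


def _db_change_spectrum(tfr: TimeFreqPower, band: tuple[float, float],
                        stim_win: tuple[float, float],
                        base_win: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    fmask = tfr.band_mask(band)
    smask, bmask = tfr.time_mask(*stim_win), tfr.time_mask(*base_win)
    p_stim = tfr.power[np.ix_(fmask, smask)].mean(axis=1)
    p_base = tfr.power[np.ix_(fmask, bmask)].mean(axis=1)
    return tfr.freqs[fmask], 10.0 * np.log10(p_stim / p_base)


def peak_frequency(tfr: TimeFreqPower, band: tuple[float, float],
                   stim_win: tuple[float, float] = STIM_WIN,
                   base_win: tuple[float, float] = BASE_WIN,
                   sign: int = 1) -> PeakFrequency:
    """Frequency of the largest strict local maximum of the dB-change spectrum.

    ``sign=-1`` searches for the deepest trough instead, appropriate for
    responses that are power *decreases* (the alpha desynchronisation).
    If the spectrum is monotone across the band (no interior local
    extremum), the band argmax is returned with ``endpoint_fallback=True``.
    """
    freqs, spec = _db_change_spectrum(tfr, band, stim_win, base_win)
    spec = sign * spec
    if len(freqs) < 3:
        raise ValueError("need at least 3 frequency bins for peak detection")
    peaks, _ = signal.find_peaks(spec)
    if peaks.size:
        best = peaks[np.argmax(spec[peaks])]
        return PeakFrequency(freq_hz=float(freqs[best]), endpoint_fallback=False)
    return PeakFrequency(freq_hz=float(freqs[np.argmax(spec)]), endpoint_fallback=True)


def baseline_band_power(tfr: TimeFreqPower, band: tuple[float, float],
                        base_win: tuple[float, float] = BASE_WIN) -> float:
    """Mean absolute (not baseline-normalised) band power in the baseline."""
    fmask = tfr.band_mask(band)
    bmask = tfr.time_mask(*base_win)
    return float(tfr.power[np.ix_(fmask, bmask)].mean())
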