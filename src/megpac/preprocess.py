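"""Pre-processing chain: band-pass / band-stop filtering, epoching, decimation.

The chain mirrors standard MEG practice for induced-oscillation studies:
a broadband fourth-order Butterworth band-pass (0.5-250 Hz) applied
bidirectionally (zero phase), sequential band-stops at the power-line
frequency and its harmonics, epoching around stimulus onset with generous
edge padding, and polyphase down-sampling to a 300 Hz analysis rate.
All IIR filters are designed as second-order sections for numerical
stability at narrow relative bandwidths.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "FilterSpec",
    "butter_filter",
    "notch_harmonics",
    "epoch_continuous",
    "decimate",
]


@dataclass
class FilterSpec:
    """Butterworth filter description."""

    kind: str  # "bandpass" | "bandstop"
    low_hz: float
    high_hz: float
    order: int = 4
    bidirectional: bool = True

    def validate(self, fs: float) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        nyq = fs / 2.0
        if not (0.0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < Nyquist ({nyq})")
        if self.high_hz > 0.99 * nyq:
            raise ValueError(
                f"corner {self.high_hz} Hz too close to Nyquist {nyq} Hz; "
                "filter design would be unstable")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def butter_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth band filter along the last axis.

    Bidirectional application (``sosfiltfilt``) gives zero phase shift and
    squares the magnitude response; output length equals input length.
    """
    spec.validate(fs)
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype=spec.kind, fs=fs, output="sos")
    if spec.bidirectional:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def notch_harmonics(x: np.ndarray, fs: float, base_hz: float = 50.0,
                    n_harmonics: int = 3, half_width_hz: float = 1.0,
                    order: int = 4) -> np.ndarray:
    """Sequential band-stops at ``base_hz`` and its harmonics.

    Removes power-line contamination at base, 2*base, ... n_harmonics*base.
    All requested harmonics must lie below Nyquist.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    top = n_harmonics * base_hz + half_width_hz
    if top >= fs / 2.0:
        raise ValueError(
            f"harmonic band up to {top} Hz exceeds Nyquist {fs / 2.0} Hz")
    out = np.asarray(x, dtype=np.float64)
    for k in range(1, n_harmonics + 1):
        f0 = k * base_hz
        spec = FilterSpec("bandstop", f0 - half_width_hz, f0 + half_width_hz, order=order)
        out = butter_filter(out, fs, spec)
    return out


def epoch_continuous(x: np.ndarray, fs: float, onsets: np.ndarray,
                     pre_s: float = 1.5, post_s: float = 1.5,
                     pad_s: float = 2.5, subject_id: str = "",
                     group: str = "") -> EpochSet:
    """Cut a continuous recording into padded stimulus-locked epochs.

    Each epoch spans [-(pre+pad), +(post+pad)) s around its onset sample;
    the time axis is zero at onset.  Onsets whose window would fall
    outside the recording are rejected with their indices reported.

    ``x`` may be 1-D (single channel) or (n_channels, n_samples).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_total = x.shape[1]
    onsets = np.asarray(onsets, dtype=np.int64)
    n_pre = int(round((pre_s + pad_s) * fs))
    n_post = int(round((post_s + pad_s) * fs))
    bad = onsets[(onsets - n_pre < 0) | (onsets + n_post > n_total)]
    if bad.size:
        raise ValueError(
            f"onsets {bad.tolist()} leave the epoch window "
            f"[-{n_pre}, +{n_post}) samples outside the recording of {n_total} samples")
    data = np.stack([x[:, o - n_pre:o + n_post] for o in onsets], axis=0)
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    return EpochSet(data=data, fs=fs, times=times, subject_id=subject_id,
                    group=group, pad_s=pad_s)


def decimate(epochs: EpochSet, target_fs: float = 300.0,
             antialias_corner_hz: float | None = None,
             antialias_order: int = 8) -> EpochSet:
    """Down-sample epochs to ``target_fs`` with explicit anti-aliasing.

    A zero-phase Butterworth low-pass (default corner 0.45 * target_fs)
    precedes polyphase resampling, so band-limited content well below the
    new Nyquist is preserved while nothing aliases.
    """
    fs = epochs.fs
    if target_fs >= fs:
        raise ValueError(f"target_fs {target_fs} must be below current fs {fs}")
    corner = 0.45 * target_fs if antialias_corner_hz is None else antialias_corner_hz
    if corner >= target_fs / 2.0:
        raise ValueError(
            f"anti-alias corner {corner} Hz must lie below the output Nyquist "
            f"{target_fs / 2.0} Hz")
    sos = signal.butter(antialias_order, corner, btype="lowpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(filtered, up, down, axis=-1)
    n_out = data.shape[-1]
    times = epochs.times[0] + np.arange(n_out) / target_fs
    return epochs.copy_with(data=data, times=times, fs=target_fs)
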