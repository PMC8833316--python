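"""Basic figures: comodulograms and time-frequency spectra."""

from __future__ import annotations

import numpy as np

from .pac import Comodulogram
from .spectral import TimeFreqPower


def plot_comodulogram(comod: Comodulogram, ax=None, **imshow_kw):
    """Phase x amplitude PAC matrix as an image (phase on x, amplitude on y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.max(np.abs(comod.values))
    kw = dict(origin="lower", aspect="auto",
              extent=(comod.phase_freqs[0], comod.phase_freqs[-1],
                      comod.amp_freqs[0], comod.amp_freqs[-1]))
    if comod.corrected:
        kw.update(cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    kw.update(imshow_kw)
    im = ax.imshow(comod.values.T, **kw)
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    ax.set_title(("baseline-corrected " if comod.corrected else "") + "PAC")
    ax.figure.colorbar(im, ax=ax, label="MVL" + (" change" if comod.corrected else ""))
    return ax


def plot_tfr(tfr: TimeFreqPower, ax=None, db_baseline: tuple[float, float] | None = None,
             **imshow_kw):
    """Time-frequency power; optionally dB-normalised to a baseline window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    power = tfr.power
    label = "power"
    if db_baseline is not None:
        base = power[:, tfr.time_mask(*db_baseline)].mean(axis=1, keepdims=True)
        power = 10.0 * np.log10(power / base)
        label = "dB re baseline"
    kw = dict(origin="lower", aspect="auto",
              extent=(tfr.times[0], tfr.times[-1], tfr.freqs[0], tfr.freqs[-1]))
    kw.update(imshow_kw)
    im = ax.imshow(power, **kw)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax
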