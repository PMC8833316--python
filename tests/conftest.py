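"""Shared fixtures: small simulated subjects and the toy source model."""

from __future__ import annotations

import numpy as np
import pytest

from megpac import (SubjectSimConfig, VirtualElectrode, decimate,
                    make_toy_source_model, simulate_subject)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_source_model()


@pytest.fixture(scope="session")
def coupled_ve():
    """Strongly coupled subject at the 300 Hz analysis rate (30 trials)."""
    cfg = SubjectSimConfig(n_trials=30, seed=11, coupling_m=0.8,
                           alpha_freq=10.0, gamma_freq=55.0)
    return VirtualElectrode.from_epochs(decimate(simulate_subject(cfg), 300.0))


def sim_ve(fs: float = 300.0, **cfg_kw) -> VirtualElectrode:
    """Simulate a subject directly at the analysis rate and return its VE."""
    cfg = SubjectSimConfig(fs_raw=fs, **cfg_kw)
    return VirtualElectrode.from_epochs(simulate_subject(cfg))


def tone_ve(freq: float, fs: float = 300.0, n_trials: int = 10,
            amp_pre: float = 1.0, amp_post: float = 1.0,
            pre_s: float = 1.5, post_s: float = 1.5, pad_s: float = 1.0,
            noise: float = 0.0, seed: int = 0) -> VirtualElectrode:
    """Sinusoid epochs with an amplitude step at onset (random phase).

    ``noise`` adds a white floor, needed when a test requires the band
    change to be localised at the tone rather than uniform.
    """
    rng = np.random.default_rng(seed)
    fs = float(fs)
    n_pre = int(round((pre_s + pad_s) * fs))
    n_post = int(round((post_s + pad_s) * fs))
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    amp = np.where(times >= 0, amp_post, amp_pre)
    data = np.stack([
        amp * np.cos(2 * np.pi * freq * times + rng.uniform(0, 2 * np.pi))
        + noise * rng.standard_normal(len(times))
        for _ in range(n_trials)
    ])
    return VirtualElectrode(data=data, fs=fs, times=times, pad_s=pad_s)
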