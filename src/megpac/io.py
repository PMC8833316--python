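"""Epoch container file format and pipeline configuration.

Epochs travel between pipeline stages as one HDF5 file per subject:

    /data   float64, (n_trials, n_channels, n_samples)
    /times  float64, (n_samples,) seconds, zero at stimulus onset
    attrs:  schema_version, fs, subject_id, group, pad_s, meta (JSON)

The format is lossless for everything the analysis needs, including the
simulator's ground-truth attributes, and is versioned so stale files fail
loudly rather than silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import EpochSet
from .synth import CohortSpec, GroupSpec, SubjectSimConfig

__all__ = [
    "SCHEMA_VERSION",
    "write_epochs",
    "read_epochs",
    "PipelineConfig",
    "config_hash",
]

SCHEMA_VERSION = "1"

_REQUIRED_ATTRS = ("schema_version", "fs", "subject_id", "group", "pad_s")


class SchemaError(ValueError):
    """Raised when an epoch file does not match the declared schema."""


def write_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write an EpochSet to the HDF5 container (overwrites)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["group"] = epochs.group
        f.attrs["pad_s"] = float(epochs.pad_s)
        f.attrs["meta"] = json.dumps(epochs.meta, sort_keys=True, default=float)


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet, validating schema version and required fields."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"epoch file {path} is missing attribute {name!r}")
        version = str(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"epoch file {path} has schema version {version}, expected {SCHEMA_VERSION}")
        for name in ("data", "times"):
            if name not in f:
                raise SchemaError(f"epoch file {path} is missing dataset {name!r}")
        meta = json.loads(f.attrs.get("meta", "{}"))
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            times=f["times"][()],
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
            pad_s=float(f.attrs["pad_s"]),
            meta=meta,
        )


@dataclass
class PipelineConfig:
    """End-to-end replication experiment settings.

    Defaults mirror the analysis conventions throughout: 0.5-250 Hz
    band-pass, 50 Hz notches, 300 Hz analysis rate, lambda 5% LCMV,
    0.3-1.5 s stimulus vs -1.5 to -0.3 s baseline windows, 7-13 x
    34-100 Hz PAC grid, 10 000-relabeling cluster test at 0.025 per tail.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    # pre-processing
    bandpass: tuple[float, float] = (0.5, 250.0)
    filter_order: int = 4
    notch_base_hz: float = 50.0
    notch_harmonics: int = 3
    notch_half_width_hz: float = 1.0
    target_fs: float = 300.0
    # sensor simulation / beamformer
    n_sensors: int = 30
    grid_shape: tuple[int, int, int] = (4, 4, 4)
    sensor_noise_amp: float = 20.0
    source_index: int | None = None  # default: central ROI grid point
    gamma_band: tuple[float, float] = (40.0, 70.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    lambda_pct: float = 5.0
    stim_win: tuple[float, float] = (0.3, 1.5)
    base_win: tuple[float, float] = (-1.5, -0.3)
    # spectral
    gamma_freq_step: float = 2.0
    gamma_win_s: float = 0.5
    gamma_step_s: float = 0.02
    gamma_smooth_hz: float = 7.0
    alpha_win_s: float = 0.5
    alpha_step_s: float = 0.1
    # PAC
    phase_freqs: tuple[float, float, float] = (7.0, 13.0, 1.0)   # start, stop, step
    amp_freqs: tuple[float, float, float] = (34.0, 100.0, 2.0)
    phase_half_bw: float = 1.0
    amp_half_bw: float = 13.0
    # stats
    n_perm: int = 10000
    perm_seed: int = 0
    connectivity: int = 4
    cluster_stat: str = "max"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("group_a", "group_b"):
                if key in c and isinstance(c[key], dict):
                    g = dict(c[key])
                    if "base" in g and isinstance(g["base"], dict):
                        g["base"] = SubjectSimConfig(**g["base"])
                    c[key] = GroupSpec(**g)
            d["cohort"] = CohortSpec(**c)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        # YAML round-trips tuples as lists; normalise
        for f_ in dataclasses.fields(cls):
            v = getattr(cfg, f_.name)
            if isinstance(v, list):
                setattr(cfg, f_.name, tuple(v))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=float)), fh,
                           sort_keys=True)

    def phase_freq_grid(self) -> np.ndarray:
        lo, hi, step = self.phase_freqs
        return np.arange(lo, hi + 1e-9, step)

    def amp_freq_grid(self) -> np.ndarray:
        lo, hi, step = self.amp_freqs
        return np.arange(lo, hi + 1e-9, step)

    def gamma_freq_grid(self) -> np.ndarray:
        return np.arange(self.gamma_band[0], self.gamma_band[1] + 1e-9,
                         self.gamma_freq_step)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for provenance stamps."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
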