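"""LCMV beamforming on a toy source model.

The spatial filter for a grid point with (fixed-orientation) lead-field
column l is

    w = (l' C^-1 l)^-1 l' C^-1,

the linearly constrained minimum variance solution: output variance is
minimised subject to unit gain (w'l = 1) at the target location.  The
sensor covariance C is estimated band-limited from the concatenation of
baseline and stimulus windows and Tikhonov-regularised by a percentage of
its mean diagonal ("lambda 5%").  Source power through a filter is the
quadratic form w' C_window w, and stimulus-induced change is expressed in
dB re baseline.

The source model here is deliberately schematic — a spherical sensor cap
and a cubic grid with smooth distance-decay lead fields — sufficient to
exercise unit gain, regularisation and point-source recovery without any
head-geometry physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, VirtualElectrode
from .preprocess import FilterSpec, butter_filter

__all__ = [
    "SourceModel",
    "SpatialFilter",
    "PowerMap",
    "make_toy_source_model",
    "covariance_window",
    "regularize",
    "lcmv_filter",
    "source_power_map",
    "select_roi_peak",
    "virtual_electrode",
]


@dataclass
class SourceModel:
    """Sensor geometry, source grid, lead field and ROI labels."""

    sensor_positions: np.ndarray  # (n_sensors, 3)
    grid_points: np.ndarray       # (n_grid, 3)
    leadfield: np.ndarray         # (n_sensors, n_grid), fixed orientation
    roi_mask: np.ndarray          # (n_grid,) bool

    def __post_init__(self) -> None:
        self.sensor_positions = np.asarray(self.sensor_positions, float)
        self.grid_points = np.asarray(self.grid_points, float)
        self.leadfield = np.asarray(self.leadfield, float)
        self.roi_mask = np.asarray(self.roi_mask, bool)
        if not np.all(np.isfinite(self.leadfield)):
            raise ValueError("leadfield must be finite")
        if self.leadfield.shape != (self.n_sensors, self.n_grid):
            raise ValueError("leadfield shape does not match sensors x grid")
        if self.roi_mask.shape != (self.n_grid,):
            raise ValueError("roi_mask length does not match grid")
        if not self.roi_mask.any():
            raise ValueError("roi_mask must select at least one grid point")
        norms = np.linalg.norm(self.leadfield, axis=0)
        if np.any(norms == 0):
            raise ValueError("leadfield contains a zero column")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_grid(self) -> int:
        return self.grid_points.shape[0]


@dataclass
class SpatialFilter:
    """Per-sensor LCMV weights for one grid point."""

    weights: np.ndarray
    grid_index: int
    lambda_pct: float = 5.0
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)


@dataclass
class PowerMap:
    """Per-grid-point dB change plus the covariance used for the filters."""

    values_db: np.ndarray
    band: tuple[float, float]
    lambda_pct: float
    cov_reg: np.ndarray = field(repr=False)


def make_toy_source_model(n_sensors: int = 30, grid_shape: tuple[int, int, int] = (4, 4, 4),
                          cap_radius: float = 0.12, grid_half_extent: float = 0.05,
                          decay_eps: float = 1e-4) -> SourceModel:
    """Build the schematic sensor cap + cubic grid model.

    Sensors sit on the upper spherical cap of radius ``cap_radius`` (m) on
    a Fibonacci spiral; the grid is a regular lattice in the cube of
    half-extent ``grid_half_extent`` around the origin (grid spacing plays
    the role of the 8 mm source grid).  Lead-field weights decay smoothly
    with sensor-source distance, L[s, g] = 1 / (d(s, g)^2 + eps).

    The ROI ("calcarine" stand-in) is the posterior face of the lattice:
    all grid points at the minimum y coordinate.
    """
    k = np.arange(n_sensors)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # z from 0.35..0.95 of the sphere: an upper cap, no sensors at the rim
    z = 0.35 + 0.6 * (k + 0.5) / n_sensors
    theta = 2.0 * np.pi * k / golden
    r_xy = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    sensors = cap_radius * np.column_stack([r_xy * np.cos(theta),
                                            r_xy * np.sin(theta), z])
    axes = [np.linspace(-grid_half_extent, grid_half_extent, s) for s in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d2 = ((sensors[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
    leadfield = 1.0 / (d2 + decay_eps)
    roi = np.isclose(grid[:, 1], grid[:, 1].min())
    return SourceModel(sensor_positions=sensors, grid_points=grid,
                       leadfield=leadfield, roi_mask=roi)


def covariance_window(epochs: EpochSet, t_start: float, t_end: float,
                      band: tuple[float, float] | None = None,
                      filter_order: int = 4) -> np.ndarray:
    """Trial-averaged sensor covariance of a (band-limited) time window.

    The band filter is applied over the full padded epoch before the
    window is cut, so filter edge effects stay in the padding.
    """
    data = epochs.data
    if band is not None:
        spec = FilterSpec("bandpass", band[0], band[1], order=filter_order)
        data = butter_filter(data, epochs.fs, spec)
        if t_end - t_start < 3.0 / band[0]:
            warnings.warn(
                f"covariance window {t_end - t_start:.3f} s is shorter than 3 cycles "
                f"of the band low edge {band[0]} Hz", stacklevel=2)
    mask = epochs.time_mask(t_start, t_end)
    if not mask.any():
        raise ValueError(f"window [{t_start}, {t_end}) not covered by epoch times")
    seg = data[:, :, mask]
    n = seg.shape[0] * seg.shape[2]
    flat = np.swapaxes(seg, 0, 1).reshape(epochs.n_channels, n)
    return flat @ flat.T / n


def regularize(cov: np.ndarray, lambda_pct: float = 5.0) -> np.ndarray:
    """Diagonal (Tikhonov) loading: C + (lambda/100) * mean(diag(C)) * I."""
    if lambda_pct < 0:
        raise ValueError("lambda_pct must be >= 0")
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    return cov + (lambda_pct / 100.0) * np.mean(np.diag(cov)) * np.eye(cov.shape[0])


def lcmv_filter(model: SourceModel, grid_index: int, cov_reg: np.ndarray,
                lambda_pct: float = 5.0,
                band: tuple[float, float] | None = None) -> SpatialFilter:
    """LCMV weights for one grid point: w = (l' C^-1 l)^-1 l' C^-1."""
    lead = model.leadfield[:, grid_index]
    if np.allclose(lead, 0.0):
        raise ValueError(f"zero lead-field column at grid index {grid_index}")
    sol = np.linalg.solve(cov_reg, lead)
    w = sol / (lead @ sol)
    return SpatialFilter(weights=w, grid_index=int(grid_index),
                         lambda_pct=lambda_pct, band=band)


def source_power_map(epochs: EpochSet, model: SourceModel,
                     band: tuple[float, float],
                     stim_win: tuple[float, float] = (0.3, 1.5),
                     base_win: tuple[float, float] = (-1.5, -0.3),
                     lambda_pct: float = 5.0) -> PowerMap:
    """Stimulus-induced band power change (dB) at every grid point.

    Common filters are computed per grid point from the regularised,
    sample-weighted average of the baseline- and stimulus-window
    covariances; power through each filter is the quadratic form w'Cw, so
    the map value is 10*log10(w'C_stim w / w'C_base w).
    """
    if epochs.n_channels != model.n_sensors:
        raise ValueError("epoch channel count does not match model sensors")
    c_stim = covariance_window(epochs, stim_win[0], stim_win[1], band)
    c_base = covariance_window(epochs, base_win[0], base_win[1], band)
    n_s = int(epochs.time_mask(*stim_win).sum())
    n_b = int(epochs.time_mask(*base_win).sum())
    c_common = (n_s * c_stim + n_b * c_base) / (n_s + n_b)
    c_reg = regularize(c_common, lambda_pct)
    # all filters at once: solve C W0 = L, then normalise each column
    w0 = np.linalg.solve(c_reg, model.leadfield)
    gains = np.einsum("sg,sg->g", model.leadfield, w0)
    w_all = w0 / gains[None, :]
    p_stim = np.einsum("sg,st,tg->g", w_all, c_stim, w_all)
    p_base = np.einsum("sg,st,tg->g", w_all, c_base, w_all)
    values = 10.0 * np.log10(p_stim / p_base)
    return PowerMap(values_db=values, band=tuple(band), lambda_pct=lambda_pct,
                    cov_reg=c_reg)


def select_roi_peak(power_map: PowerMap | np.ndarray, model: SourceModel) -> int:
    """Grid index of the largest dB change inside the ROI.

    Ties break to the lowest grid index (first occurrence), so selection
    is deterministic.  NaN map values are ignored; an all-NaN ROI is an
    error.
    """
    values = power_map.values_db if isinstance(power_map, PowerMap) else np.asarray(power_map)
    roi_vals = np.where(model.roi_mask, values, -np.inf)
    roi_vals = np.where(np.isnan(roi_vals), -np.inf, roi_vals)
    if not np.isfinite(roi_vals).any():
        raise ValueError("no finite map values inside the ROI")
    return int(np.argmax(roi_vals))


def virtual_electrode(epochs: EpochSet, filt: SpatialFilter) -> VirtualElectrode:
    """Project broadband sensor epochs through one grid point's weights."""
    if epochs.n_channels != filt.weights.shape[0]:
        raise ValueError(
            f"filter has {filt.weights.shape[0]} weights but epochs have "
            f"{epochs.n_channels} channels")
    data = np.einsum("c,tcs->ts", filt.weights, epochs.data)
    ve = VirtualElectrode(data=data, fs=epochs.fs, times=epochs.times,
                          subject_id=epochs.subject_id, group=epochs.group,
                          pad_s=epochs.pad_s, meta=dict(epochs.meta))
    ve.meta["ve_grid_index"] = filt.grid_index
    ve.meta["ve_lambda_pct"] = filt.lambda_pct
    return ve
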