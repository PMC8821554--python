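"""LCMV beamforming on ROI grids with 60%-of-peak vertex selection.

A common data covariance is estimated from all conditions combined
(baseline plus the 1.5 s windows after pulses 1-3, with +/-5 ms around
each stimulation excised), so one unbiased spatial filter serves every
condition.  Per grid point the unit-gain minimum-variance filter is

    w = C_reg^{-1} l / (l^T C_reg^{-1} l),      w^T l = 1,

with the max-power orientation for 3-column leadfields and diagonal
loading C_reg = C + lambda * mean(diag C) * I.  Source power per condition
is contrasted against baseline, vertices above 60% of the ROI peak
contrast are kept, and their filter outputs are averaged into one
single-trial time series per ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import CONDITIONS, LeadfieldModel

EXCISION_HALF_WIDTH_S = 0.005
VERTEX_POWER_FRACTION = 0.60
DEFAULT_REGULARIZATION = 0.05


@dataclass
class SpatialFilter:
    weights: np.ndarray      # (n_channels,)
    orientation: np.ndarray | None  # (3,) for vector leadfields
    point: int


@dataclass
class ROITimeSeries:
    roi: str
    selected_points: np.ndarray
    series: dict  # condition -> (n_trials, n_samples)
    fs: float
    contrasts: np.ndarray  # per-point baseline contrast used for selection


def excision_mask(n_samples: int, fs: float, pulse_sample: int | None
                  ) -> np.ndarray:
    """Boolean mask of retained samples; +/-5 ms around the pulse excised."""
    keep = np.ones(n_samples, dtype=bool)
    if pulse_sample is not None:
        half = int(round(EXCISION_HALF_WIDTH_S * fs))
        lo = max(pulse_sample - half, 0)
        hi = min(pulse_sample + half + 1, n_samples)
        keep[lo:hi] = False
    return keep


def compute_covariance(epochs_by_condition, fs: float,
                       pulse_sample: int | None = 0) -> np.ndarray:
    """Channel covariance pooled over all conditions.

    ``epochs_by_condition`` maps condition -> (n_trials, n_channels,
    n_samples).  Epochs are demeaned per channel; excised samples (around
    the stimulation instant of pulse conditions) are omitted.
    """
    total = None
    count = 0
    n_ch = None
    for cond, x in epochs_by_condition.items():
        x = np.asarray(x, dtype=float)
        n_trials, nc, n_samp = x.shape
        n_ch = nc
        keep = excision_mask(n_samp, fs,
                             pulse_sample if cond != "baseline" else None)
        if not keep.any():
            raise ValueError("excision removed all samples")
        xs = x[:, :, keep]
        xs = xs - xs.mean(axis=2, keepdims=True)
        flat = xs.transpose(1, 0, 2).reshape(nc, -1)
        c = flat @ flat.T
        total = c if total is None else total + c
        count += flat.shape[1]
    if count <= (n_ch or 0):
        raise ValueError("fewer effective samples than channels")
    cov = total / count
    return 0.5 * (cov + cov.T)


def lcmv_filter(leadfield: np.ndarray, cov: np.ndarray,
                regularization: float = DEFAULT_REGULARIZATION,
                point: int = -1) -> SpatialFilter:
    """Unit-gain LCMV weights for one grid point.

    ``leadfield`` is (n_channels,) for fixed orientation or
    (n_channels, 3); for the latter the max-power orientation (minimum of
    the reduced 3x3 problem l^T C^{-1} l) is chosen first.
    """
    l = np.asarray(leadfield, dtype=float)
    c = np.asarray(cov, dtype=float)
    creg = c + regularization * np.mean(np.diag(c)) * np.eye(c.shape[0])
    try:
        cinv = np.linalg.inv(creg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance singular after regularization") from err
    orientation = None
    if l.ndim == 2:
        m = l.T @ cinv @ l  # 3x3; power(u) = 1 / (u^T m u)
        vals, vecs = np.linalg.eigh(0.5 * (m + m.T))
        orientation = vecs[:, 0]
        l = l @ orientation
    denom = float(l @ cinv @ l)
    if denom <= 0:
        raise np.linalg.LinAlgError("degenerate leadfield projection")
    w = cinv @ l / denom
    return SpatialFilter(weights=w, orientation=orientation, point=point)


def source_power(filt: SpatialFilter, epochs: np.ndarray, fs: float,
                 pulse_sample: int | None = None) -> float:
    """Mean squared filter output over the window, excision-aware."""
    x = np.asarray(epochs, dtype=float)
    keep = excision_mask(x.shape[2], fs, pulse_sample)
    y = np.einsum("c,tcs->ts", filt.weights, x[:, :, keep])
    return float(np.mean(y ** 2))


def source_power_contrast(filters, epochs_by_condition, fs: float,
                          pulse_sample: int | None = 0) -> np.ndarray:
    """(n_points, n_pulse_conditions) baseline-contrasted power:
    (P_cond - P_base) / P_base per grid point."""
    pulse_conds = [c for c in CONDITIONS if c != "baseline"
                   and c in epochs_by_condition]
    out = np.empty((len(filters), len(pulse_conds)))
    for i, filt in enumerate(filters):
        p_base = source_power(filt, epochs_by_condition["baseline"], fs, None)
        for j, cond in enumerate(pulse_conds):
            p = source_power(filt, epochs_by_condition[cond], fs,
                             pulse_sample)
            out[i, j] = (p - p_base) / p_base
    return out


def select_vertices_and_extract(filters, contrasts: np.ndarray,
                                epochs_by_condition, fs: float, roi: str,
                                threshold: float = VERTEX_POWER_FRACTION
                                ) -> ROITimeSeries:
    """Keep grid points whose contrast reaches ``threshold`` x the ROI peak
    (max over pulse conditions) and average their filter outputs into one
    trial-by-trial series per condition.

    If every contrast is non-positive the single peak point is kept with a
    warning.
    """
    if len(filters) == 0:
        raise ValueError("empty ROI")
    per_point = np.asarray(contrasts).max(axis=1)
    peak = per_point.max()
    if peak <= 0:
        warnings.warn(f"ROI {roi!r}: all contrasts non-positive; "
                      "falling back to the peak point", stacklevel=2)
        sel = np.array([int(np.argmax(per_point))])
    else:
        sel = np.flatnonzero(per_point >= threshold * peak)
    w = np.stack([filters[i].weights for i in sel])
    series = {}
    for cond, x in epochs_by_condition.items():
        x = np.asarray(x, dtype=float)
        series[cond] = np.einsum("pc,tcs->ts", w, x) / len(sel)
    return ROITimeSeries(roi=roi, selected_points=sel, series=series,
                         fs=fs, contrasts=per_point)


def beamform_roi(sensor_epochs, leadfields: LeadfieldModel, roi: str,
                 fs: float, pulse_sample: int | None = 0,
                 regularization: float = DEFAULT_REGULARIZATION
                 ) -> ROITimeSeries:
    """Full chain for one ROI: covariance -> filters -> contrasts ->
    vertex selection -> ROI trial series."""
    cov = compute_covariance(sensor_epochs, fs, pulse_sample)
    idx = np.flatnonzero(leadfields.roi_label == roi)
    if len(idx) == 0:
        raise ValueError(f"no grid points labeled {roi!r}")
    filters = [lcmv_filter(leadfields.leadfield[i], cov, regularization,
                           point=int(i)) for i in idx]
    contrasts = source_power_contrast(filters, sensor_epochs, fs,
                                      pulse_sample)
    return select_vertices_and_extract(filters, contrasts, sensor_epochs,
                                       fs, roi)
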