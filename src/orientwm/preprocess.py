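"""Temporal detrending, temporal smoothing, trial sample extraction,
feature-space smoothing, and score-based voxel selection.

Detrending removes slow per-run signal drifts with an interpolating cubic
spline through segment-mean nodes; the node count is half the trial count,
coarse enough not to absorb within-trial structure. Feature-space smoothing
is the SNR-raising step specific to feature-continuous designs: each trial's
voxel pattern is replaced by a Gaussian-weighted average over trials with
nearby *orientation labels* (circular distance, period 180°).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import convolve1d

from ._circ import circ_diff_180

__all__ = ["SmoothingSpec", "TrialSamples", "spline_detrend", "temporal_smooth",
           "extract_trial_samples", "feature_space_smooth", "smoothing_weights",
           "select_voxels"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class SmoothingSpec:
    """Feature-space smoothing kernel: Gaussian in circular orientation
    distance, parameterized by its full width at half maximum (degrees).

    ``scope="run"`` restricts the weighted average to trials of the same run
    so that leave-one-run-out folds never share smoothed information;
    ``scope="all"`` pools across runs (measurably leaky, kept for
    comparison).
    """

    fwhm_deg: float = 0.0
    kernel: str = "gaussian-circular-180"
    scope: str = "run"

    def __post_init__(self):
        if self.fwhm_deg < 0:
            raise ValueError("fwhm_deg must be nonnegative")
        if self.scope not in ("run", "all"):
            raise ValueError("scope must be 'run' or 'all'")


@dataclass
class TrialSamples:
    """Trial × voxel matrix at a fixed TR offset, with labels and run ids."""

    X: np.ndarray            # (n_trials, n_voxels)
    labels: np.ndarray       # orientation label per trial, degrees in [0,180)
    run_ids: np.ndarray      # run index per trial

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.run_ids = np.asarray(self.run_ids)
        if not (len(self.X) == len(self.labels) == len(self.run_ids)):
            raise ValueError("X, labels and run_ids must align")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("samples must be finite")

    @property
    def n_trials(self):
        return self.X.shape[0]


def _detrend_operator(n_time, n_nodes):
    """Node abscissae and the linear map from node values to the spline's
    per-segment means; cached per (n_time, n_nodes)."""
    key = (int(n_time), int(n_nodes))
    if key not in _detrend_operator._cache:
        segments = np.array_split(np.arange(n_time), n_nodes)
        node_x = np.array([seg.mean() for seg in segments])
        t = np.arange(n_time)
        basis = CubicSpline(node_x, np.eye(n_nodes), axis=0)(t)  # (T, nodes)
        seg_mean = np.vstack([basis[seg].mean(axis=0) for seg in segments])
        _detrend_operator._cache[key] = (segments, node_x, seg_mean)
    return _detrend_operator._cache[key]


_detrend_operator._cache = {}


def spline_detrend(run_series, n_trials=None, n_nodes=None, return_nodes=False):
    """Remove slow drifts from one run's timepoints × voxels series.

    The run is split into ``n_trials/2`` equal-size segments (or an explicit
    ``n_nodes``), one node per segment at the segment center, and a cubic
    spline through the nodes is subtracted per voxel. Node values are chosen
    so that the fitted drift's per-segment means equal the data's
    per-segment means (for a constant or linear drift these coincide with
    the plain segment averages); that makes the detrender a projection, so
    applying it twice changes nothing.

    For an odd ``n_trials`` the half-trial node rule is undefined — pass
    ``n_nodes`` explicitly in that case.
    """
    series = np.atleast_2d(np.asarray(run_series, dtype=float))
    if n_nodes is None:
        if n_trials is None:
            raise ValueError("provide n_trials or n_nodes")
        if n_trials % 2:
            raise ValueError("n_trials is odd: the half-trial node rule is "
                             "undefined; pass n_nodes explicitly")
        n_nodes = n_trials // 2
    if n_nodes < 2:
        raise ValueError("need at least 2 spline nodes")
    n_time = series.shape[0]
    if n_time < n_nodes:
        raise ValueError("fewer timepoints than spline nodes")
    segments, node_x, seg_mean_op = _detrend_operator(n_time, n_nodes)
    target_means = np.vstack([series[seg].mean(axis=0) for seg in segments])
    node_y = np.linalg.solve(seg_mean_op, target_means)
    trend = CubicSpline(node_x, node_y, axis=0)(np.arange(n_time))
    detrended = series - trend
    if return_nodes:
        return detrended, node_x
    return detrended


def temporal_smooth(run_series, width=3):
    """Centered moving average over timepoints; edges shrink the window to
    the available neighbors so the output keeps its length unpadded."""
    series = np.atleast_2d(np.asarray(run_series, dtype=float))
    width = int(width)
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if width > series.shape[0]:
        raise ValueError("width exceeds number of timepoints")
    if width == 1:
        return series.copy()
    kernel = np.ones(width)
    sums = convolve1d(series, kernel, axis=0, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(series.shape[0]), kernel, mode="constant",
                        cval=0.0)
    return sums / counts[:, None]


def extract_trial_samples(series, design, tr_offset=0, label_col="target_deg"):
    """Pull one voxel vector per trial at a fixed TR offset from trial onset.

    ``series`` is a :class:`~orientwm.simdata.VoxelArray`; ``design`` the
    matching trial table. Trialwise layouts only admit ``tr_offset=0``.
    """
    design = design.sort_values(["run", "trial"], kind="stable")
    n_runs, n_time, _ = series.data.shape
    if series.layout == "trialwise":
        if tr_offset != 0:
            raise ValueError("trialwise layout has a single sample per "
                             "trial; tr_offset must be 0")
    if tr_offset < 0:
        raise ValueError("tr_offset must be nonnegative")
    rows = []
    run_order = np.unique(design["run"].to_numpy())
    for r_idx, run in enumerate(run_order):
        onsets = series.onsets[r_idx]
        idx = onsets + tr_offset
        if idx.max() >= n_time:
            raise ValueError(f"tr_offset {tr_offset} falls outside run "
                             f"{run} (length {n_time})")
        rows.append(series.data[r_idx, idx, :])
    X = np.vstack(rows)
    if label_col not in design.columns:
        raise KeyError(f"design has no column {label_col!r}")
    return TrialSamples(X=X, labels=design[label_col].to_numpy(dtype=float),
                        run_ids=design["run"].to_numpy())


def smoothing_weights(labels, fwhm_deg):
    """Row-normalized Gaussian weight matrix over circular label distance.

    Row j holds the weights with which other trials contribute to trial j's
    smoothed pattern. FWHM 0 returns the identity.
    """
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    if fwhm_deg == 0:
        return np.eye(n)
    sigma = fwhm_deg * FWHM_TO_SIGMA
    dist = np.abs(circ_diff_180(labels[:, None], labels[None, :]))
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def feature_space_smooth(samples, spec):
    """Replace each trial's voxel vector by a Gaussian-weighted average of
    trials with nearby orientation labels (see :class:`SmoothingSpec`)."""
    if not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(float(spec))
    if spec.fwhm_deg == 0:
        return replace(samples, X=samples.X.copy())
    X = np.empty_like(samples.X)
    if spec.scope == "all":
        W = smoothing_weights(samples.labels, spec.fwhm_deg)
        X[:] = W @ samples.X
    else:
        for run in np.unique(samples.run_ids):
            mask = samples.run_ids == run
            W = smoothing_weights(samples.labels[mask], spec.fwhm_deg)
            X[mask] = W @ samples.X[mask]
    return replace(samples, X=X)


def select_voxels(scores, n):
    """Indices of the ``n`` highest-scoring voxels; ties resolve to the
    lowest index. Returned sorted ascending."""
    scores = np.asarray(scores, dtype=float)
    n = int(n)
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(scores):
        raise ValueError("n exceeds the number of voxels")
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:n])
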