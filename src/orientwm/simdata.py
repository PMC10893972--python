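"""Synthetic delayed-estimation datasets: trial designs, orientation-tuned
voxel populations, and behavioral reports.

The generator mirrors the study conditions it is meant to stand in for: 8
runs of 40 trials, a target set of 40 equally spaced orientations shifted
off the cardinal axes, distractors offset by half an orientation step, voxel
populations with smooth periodic tuning curves drawn from a Gaussian process
with a periodic covariance kernel (per-voxel smoothness ~ Γ(2, 2)), additive
standard-normal measurement noise scaled against the tuning signal by an SNR
factor s ∈ [0, 1], and behavioral reports from a detection/swap/guess
mixture.

Voxel signal model, per voxel i and trial j::

    y_ij = z_i(θ_j) · s + ε_ij,   ε_ij ~ N(0, 1)

with tuning curve z_i ~ N(0, K_i) on a grid of 2π-periodic "orientation
phase" values (orientation θ in degrees maps to phase 2πθ/180), and kernel
K_i(x_m, x_n) = exp(-2 sin²((x_m - x_n)/2) / σ_i²).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._circ import wrap_orientation

__all__ = [
    "N_ORIENTATIONS", "ORIENTATION_STEP", "CARDINAL_SHIFT", "DISTRACTOR_OFFSET",
    "TARGET_SET", "DISTRACTOR_SET",
    "TuningProfile", "SimConfig", "VoxelArray",
    "generate_design", "periodic_kernel", "sample_tuning_profiles",
    "simulate_voxel_responses", "expand_to_timecourse", "simulate_behavior",
    "simulate_dataset", "design_to_tsv", "design_from_tsv",
]

#: number of distinct target orientations per run
N_ORIENTATIONS = 40
#: spacing of the orientation set, 180/40 = 4.5°
ORIENTATION_STEP = 180.0 / N_ORIENTATIONS
#: offset that shifts every stimulus off the cardinal axes (0/45/90/135°)
CARDINAL_SHIFT = ORIENTATION_STEP / 4.0  # 1.125°
#: distractor offset relative to the target set, 4.5/2 = 2.25°
DISTRACTOR_OFFSET = ORIENTATION_STEP / 2.0

#: the 40 target orientations, 1.125° .. 176.625°
TARGET_SET = CARDINAL_SHIFT + ORIENTATION_STEP * np.arange(N_ORIENTATIONS)
#: the 40 distractor orientations, 3.375° .. 178.875°
DISTRACTOR_SET = TARGET_SET + DISTRACTOR_OFFSET

DESIGN_COLUMNS = ["subject", "run", "trial", "target_deg", "distractor_deg", "cue"]


def _rng(seed):
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def generate_design(n_runs, seed=None, subject="sim01"):
    """Generate a counterbalanced delayed-estimation trial table.

    Each run presents every one of the 40 target orientations exactly once
    and every one of the 40 distractor orientations exactly once, both in
    independently randomized order; the retro-cue (1 = first grating is the
    target, 2 = second) is drawn uniformly per trial. The probe grating's
    random starting orientation is drawn uniformly from [0, 180).

    Returns a DataFrame with columns
    ``subject, run, trial, target_deg, distractor_deg, cue, probe_start_deg``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _rng(seed)
    frames = []
    for run in range(1, n_runs + 1):
        targets = rng.permutation(TARGET_SET)
        distractors = rng.permutation(DISTRACTOR_SET)
        cues = rng.integers(1, 3, size=N_ORIENTATIONS)
        probe = rng.uniform(0.0, 180.0, size=N_ORIENTATIONS)
        frames.append(pd.DataFrame({
            "subject": subject,
            "run": run,
            "trial": np.arange(1, N_ORIENTATIONS + 1),
            "target_deg": targets,
            "distractor_deg": distractors,
            "cue": cues,
            "probe_start_deg": probe,
        }))
    return pd.concat(frames, ignore_index=True)


def design_to_tsv(design, path):
    design.to_csv(path, sep="\t", index=False)


def design_from_tsv(path):
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# voxel tuning and responses
# ---------------------------------------------------------------------------

def periodic_kernel(xm, xn, sigma):
    """Periodic (exponential-sine-squared) covariance kernel.

    ``K(x_m, x_n, σ) = exp(-2 sin²((x_m - x_n)/2) / σ²)``; 2π-periodic in the
    lag, symmetric, with K(x, x) = 1. Broadcasts over array inputs.
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lag = 0.5 * (np.asarray(xm, dtype=float) - np.asarray(xn, dtype=float))
    return np.exp(-2.0 * np.sin(lag) ** 2 / sigma ** 2)


@dataclass
class TuningProfile:
    """A voxel's periodic orientation tuning curve sampled on a phase grid."""

    grid: np.ndarray       # p equally spaced phase values in [0, 2π)
    values: np.ndarray     # z_i, one tuning value per grid point
    smoothness: float      # σ_i of the covariance kernel

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def phase_grid(grid_size):
    """p equally spaced orientation-phase values in [0, 2π)."""
    return np.linspace(0.0, 2.0 * np.pi, int(grid_size), endpoint=False)


def sample_tuning_profiles(n_voxels, grid_size=180, seed=None,
                           gamma_shape=2.0, gamma_scale=2.0, jitter=1e-6):
    """Draw periodic tuning curves for a voxel population.

    Per voxel, smoothness σ_i ~ Γ(shape=``gamma_shape``, scale=``gamma_scale``)
    (defaults give mean 4), then z_i ~ N(0, K_i) with K_i built from
    :func:`periodic_kernel` on the phase grid and ``jitter`` added to the
    diagonal before Cholesky factorization.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rng = _rng(seed)
    grid = phase_grid(grid_size)
    sigmas = rng.gamma(gamma_shape, gamma_scale, size=n_voxels)
    profiles = []
    for sigma in sigmas:
        cov = periodic_kernel(grid[:, None], grid[None, :], sigma)
        cov[np.diag_indices_from(cov)] += jitter
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise RuntimeError(
                f"periodic kernel matrix not positive definite after jitter "
                f"{jitter:g} (sigma={sigma:.4g}, grid_size={grid_size})"
            ) from err
        values = chol @ rng.standard_normal(grid_size)
        profiles.append(TuningProfile(grid=grid, values=values, smoothness=float(sigma)))
    return profiles


# ---------------------------------------------------------------------------
# voxel signal containers
# ---------------------------------------------------------------------------

@dataclass
class VoxelArray:
    """Runs × timepoints (or trials) × voxels signal container.

    ``layout`` is ``"trialwise"`` (one sample per trial) or ``"timecourse"``
    (TR-resolved series with trial onsets). ``onsets`` holds, per run, the
    timepoint index of each trial's onset (for trialwise data this is simply
    the trial index).
    """

    data: np.ndarray           # (n_runs, n_time, n_voxels)
    layout: str                # "trialwise" | "timecourse"
    onsets: np.ndarray         # (n_runs, n_trials)
    tr_seconds: float = 0.8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.layout not in ("trialwise", "timecourse"):
            raise ValueError("layout must be 'trialwise' or 'timecourse'")
        if self.data.ndim != 3:
            raise ValueError("data must be (n_runs, n_time, n_voxels)")
        if self.onsets.ndim != 2 or self.onsets.shape[0] != self.data.shape[0]:
            raise ValueError("onsets must be (n_runs, n_trials)")
        if np.any(np.diff(self.onsets, axis=1) <= 0):
            raise ValueError("onsets must be strictly increasing within run")
        if self.onsets.max() >= self.data.shape[1]:
            raise ValueError("onset index out of bounds for data")

    @property
    def n_runs(self):
        return self.data.shape[0]

    @property
    def n_voxels(self):
        return self.data.shape[2]

    @property
    def n_trials_per_run(self):
        return self.onsets.shape[1]

    def subset_voxels(self, indices):
        """Return a new VoxelArray restricted to the given voxel indices."""
        return VoxelArray(self.data[:, :, np.asarray(indices, dtype=int)],
                          self.layout, self.onsets, self.tr_seconds,
                          dict(self.meta))

    def save(self, stem):
        """Write a flat float64 binary (run-major, time-major, voxel-minor)
        plus a JSON sidecar describing shape, layout, onsets and sampling."""
        stem = Path(stem)
        self.data.astype("<f8").tofile(stem.with_suffix(".bin"))
        sidecar = {
            "shape": list(self.data.shape),
            "layout": self.layout,
            "onsets": self.onsets.tolist(),
            "tr_seconds": self.tr_seconds,
            "meta": self.meta,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem):
        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        data = np.fromfile(stem.with_suffix(".bin"), dtype="<f8")
        data = data.reshape(sidecar["shape"])
        return cls(data, sidecar["layout"], np.asarray(sidecar["onsets"]),
                   sidecar.get("tr_seconds", 0.8), sidecar.get("meta", {}))


@dataclass
class SimConfig:
    """Dataset-level simulation settings."""

    n_runs: int = 8
    trials_per_run: int = N_ORIENTATIONS
    n_voxels: int = 250
    snr: float = 0.5
    grid_size: int = 180
    seed: int = 0
    gamma_shape: float = 2.0
    gamma_scale: float = 2.0

    def __post_init__(self):
        if min(self.n_runs, self.trials_per_run, self.n_voxels, self.grid_size) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.snr <= 1.0:
            raise ValueError("snr must lie in [0, 1]")


def _orientation_to_grid_index(theta_deg, grid_size):
    """Map orientation θ ∈ [0, 180) to the nearest phase-grid index."""
    theta = np.asarray(theta_deg, dtype=float)
    if np.any((theta < 0) | (theta >= 180.0)):
        raise ValueError("orientations must lie in [0, 180)")
    phase = theta * (2.0 * np.pi / 180.0)
    step = 2.0 * np.pi / grid_size
    return np.rint(phase / step).astype(int) % grid_size


def simulate_voxel_responses(profiles, design, snr, seed=None, tr_seconds=0.8):
    """Simulate trialwise voxel responses y_ij = z_i(θ_j)·s + ε_ij.

    The driving orientation is the trial's target. Returns a trialwise
    :class:`VoxelArray` of shape (n_runs, trials_per_run, n_voxels).
    """
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = _rng(seed)
    design = design.sort_values(["run", "trial"], kind="stable")
    runs = design["run"].to_numpy()
    run_ids = np.unique(runs)
    trials_per_run = np.bincount(np.searchsorted(run_ids, runs)).max()
    if len(design) != len(run_ids) * trials_per_run:
        raise ValueError("design must have the same number of trials per run")

    grid_size = len(profiles[0].grid)
    tuning = np.column_stack([p.values for p in profiles])  # (p, n_voxels)
    idx = _orientation_to_grid_index(design["target_deg"].to_numpy(), grid_size)
    signal = tuning[idx, :]                                  # (n_trials, n_voxels)
    noise = rng.standard_normal(signal.shape)
    data = (signal * snr + noise).reshape(len(run_ids), trials_per_run, -1)
    onsets = np.tile(np.arange(trials_per_run), (len(run_ids), 1))
    return VoxelArray(data, "trialwise", onsets, tr_seconds,
                      meta={"snr": float(snr), "trs_per_trial": 1})


def expand_to_timecourse(trialwise, trs_per_trial, active_window, seed=None):
    """Expand a trialwise VoxelArray into a TR-resolved timecourse.

    Each trial occupies ``trs_per_trial`` consecutive TRs. Within the
    inclusive TR range ``active_window = (lo, hi)`` (relative to trial onset)
    the trial's pattern is present; every TR additionally receives fresh
    independent unit-variance noise, so out-of-window TRs are pure noise.
    """
    if trialwise.layout != "trialwise":
        raise ValueError("input must have trialwise layout")
    lo, hi = int(active_window[0]), int(active_window[1])
    if not (0 <= lo <= hi < trs_per_trial):
        raise ValueError("active_window must be a nonempty range within "
                         "[0, trs_per_trial)")
    rng = _rng(seed)
    n_runs, n_trials, n_voxels = trialwise.data.shape
    n_time = n_trials * trs_per_trial
    data = rng.standard_normal((n_runs, n_time, n_voxels))
    for t in range(n_trials):
        start = t * trs_per_trial
        data[:, start + lo:start + hi + 1, :] += trialwise.data[:, t:t + 1, :]
    onsets = np.tile(np.arange(n_trials) * trs_per_trial, (n_runs, 1))
    meta = dict(trialwise.meta)
    meta.update({"trs_per_trial": int(trs_per_trial),
                 "active_window": [lo, hi]})
    return VoxelArray(data, "timecourse", onsets, trialwise.tr_seconds, meta)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _sample_vonmises_doubled(rng, kappa, size):
    """Von Mises error on the doubled-angle circle, returned in degrees.

    For very large κ the von Mises sampler is replaced by its normal limit
    N(0, 1/κ) to stay numerically safe near the κ cap.
    """
    if kappa > 1e5:
        draw = rng.standard_normal(size) / np.sqrt(kappa)
    else:
        draw = rng.vonmises(0.0, kappa, size=size)
    return draw * (90.0 / np.pi)


def simulate_behavior(design, params, seed=None):
    """Simulate delayed-estimation reports from the detection/swap/guess
    mixture.

    Per trial the component is drawn with probabilities (r1, r2, r3);
    detections report the target plus bias μ plus von Mises error with
    precision κ1 (on the doubled-angle circle), swaps do the same around the
    distractor with κ2, guesses are uniform over the orientation space.
    Returns a copy of the design with ``response_deg`` and ``component``
    (1=detection, 2=swap, 3=guess) columns added.
    """
    from .vmmm import VMMMParams  # local import avoids a hard cycle
    if not isinstance(params, VMMMParams):
        params = VMMMParams(*params)
    params.validate(kappa_cap=np.inf)
    rng = _rng(seed)
    design = design.reset_index(drop=True)
    n = len(design)
    comp = rng.choice([1, 2, 3], size=n, p=[params.r1, params.r2, params.r3])
    response = np.empty(n)
    for c, center_col, kappa in ((1, "target_deg", params.kappa1),
                                 (2, "distractor_deg", params.kappa2)):
        mask = comp == c
        if mask.any():
            err = _sample_vonmises_doubled(rng, max(kappa, 1e-12), mask.sum())
            response[mask] = (design.loc[mask, center_col].to_numpy()
                              + params.mu_deg + err)
    mask = comp == 3
    if mask.any():
        response[mask] = (design.loc[mask, "target_deg"].to_numpy()
                          + rng.uniform(-90.0, 90.0, mask.sum()))
    out = design.copy()
    out["response_deg"] = wrap_orientation(response)
    out["component"] = comp
    return out


def simulate_dataset(config, behavior_params=None, subject="sim01"):
    """Convenience wrapper: design + tuning + voxel responses (+ behavior).

    Uses one master seed with per-stage substreams (design, tuning, noise,
    behavior) so each stage is independently reproducible.

    Returns ``(design, voxels, profiles)``; if ``behavior_params`` is given,
    the design gains a ``response_deg`` column.
    """
    ss = np.random.SeedSequence(config.seed)
    s_design, s_tuning, s_noise, s_behavior = ss.spawn(4)
    design = generate_design(config.n_runs, seed=np.random.default_rng(s_design),
                             subject=subject)
    profiles = sample_tuning_profiles(
        config.n_voxels, config.grid_size, seed=np.random.default_rng(s_tuning),
        gamma_shape=config.gamma_shape, gamma_scale=config.gamma_scale)
    voxels = simulate_voxel_responses(profiles, design, config.snr,
                                      seed=np.random.default_rng(s_noise))
    if behavior_params is not None:
        design = simulate_behavior(design, behavior_params,
                                   seed=np.random.default_rng(s_behavior))
    return design, voxels, profiles
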