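"""Group-level statistics: cluster-mass permutation tests over accuracy
timecourses, two-sample comparisons, Pearson correlations, and the
leave-one-subject-out grid assignment of preprocessing parameters.

The cluster permutation controls the family-wise error of a time-resolved
one-sample test against chance: per TR a one-sample t versus chance forms
clusters of contiguous supra-threshold TRs, each cluster's statistic is its
summed t ("t-mass"), and the null distribution of the *maximum* cluster mass
is built by randomly sign-flipping each subject's chance-centered
timecourse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["Cluster", "PermutationResult", "ParamGrid", "cluster_permutation",
           "group_compare", "correlate", "nested_grid_assign"]


@dataclass
class Cluster:
    """A contiguous supra-threshold TR range with its t-mass and p-value."""

    tr_start: int
    tr_end: int      # inclusive
    t_mass: float
    p_value: float


@dataclass
class PermutationResult:
    clusters: list
    t_values: np.ndarray
    threshold: float
    n_permutations: int
    alpha_form: float
    seed: int | None = None

    def to_dict(self):
        return {
            "clusters": [asdict(c) for c in self.clusters],
            "t_values": np.asarray(self.t_values).tolist(),
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "alpha_form": self.alpha_form,
            "seed": self.seed,
        }

    def to_json(self, path=None):
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _cluster_masses(t_values, supra):
    """Contiguous runs of supra-threshold TRs and their summed t."""
    clusters = []
    start = None
    for i, flag in enumerate(supra):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1, float(t_values[start:i].sum())))
            start = None
    if start is not None:
        clusters.append((start, len(supra) - 1,
                         float(t_values[start:].sum())))
    return clusters


def cluster_permutation(accuracy, chance=50.0, n_perm=10000, alpha_form=0.05,
                        seed=None):
    """Cluster-based t-mass permutation test of above-chance accuracy.

    Parameters
    ----------
    accuracy : array (n_subjects, n_trs)
        Per-subject accuracy timecourses (percent).
    chance : float
        Chance level subtracted before testing (one-tailed, above chance).
    n_perm : int
        Number of random per-subject sign flips for the max-mass null.
    alpha_form : float
        One-tailed cluster-forming alpha on the per-TR one-sample t.

    Returns a :class:`PermutationResult`; cluster p-values carry the
    (1 + k) / (1 + n_perm) small-sample correction.
    """
    d = np.asarray(accuracy, dtype=float) - chance
    n_sub, n_tr = d.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    sd = d.std(axis=0, ddof=1)
    valid = sd > 0
    if not valid.all():
        warnings.warn("excluding zero-variance TRs from the cluster test",
                      stacklevel=2)
    t_obs = np.zeros(n_tr)
    t_obs[valid] = d.mean(axis=0)[valid] / (sd[valid] / np.sqrt(n_sub))
    threshold = float(stats.t.ppf(1.0 - alpha_form, df=n_sub - 1))
    supra = valid & (t_obs > threshold)
    observed = _cluster_masses(t_obs, supra)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    m = signs @ d / n_sub                                   # (n_perm, n_tr)
    msq = np.mean(d ** 2, axis=0)                           # sign-invariant
    var = (msq - m ** 2) * n_sub / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m / np.sqrt(var / n_sub)
    t_perm[:, ~valid] = 0.0
    t_perm = np.nan_to_num(t_perm)
    supra_perm = t_perm > threshold
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses = _cluster_masses(t_perm[p], supra_perm[p])
        if masses:
            null_max[p] = max(c[2] for c in masses)
    clusters = [Cluster(s, e, mass,
                        float((1 + np.sum(null_max >= mass)) / (1 + n_perm)))
                for s, e, mass in observed]
    return PermutationResult(clusters, t_obs, threshold, n_perm, alpha_form,
                             seed if isinstance(seed, int) else None)


@dataclass
class GroupComparison:
    t: float
    p: float
    df: int


def group_compare(a, b):
    """Two-tailed pooled-variance two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled <= 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(float(t), float(p), len(a) + len(b) - 2)


def correlate(x, y):
    """Pearson correlation with its two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ParamGrid:
    """Per-subject accuracy over the FWHM × voxel-count search grid.

    ``accuracy`` has shape (n_subjects, n_fwhm, n_voxel_counts, n_trs).
    """

    accuracy: np.ndarray
    fwhm_values: np.ndarray
    voxel_counts: np.ndarray

    def __post_init__(self):
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.fwhm_values = np.asarray(self.fwhm_values, dtype=float)
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        if self.accuracy.ndim != 4:
            raise ValueError("accuracy must be (subject, fwhm, voxels, tr)")
        if self.accuracy.shape[1] != len(self.fwhm_values):
            raise ValueError("fwhm axis mismatch")
        if self.accuracy.shape[2] != len(self.voxel_counts):
            raise ValueError("voxel-count axis mismatch")


def nested_grid_assign(grid, tr_window):
    """Leave-one-subject-out assignment of (FWHM, voxel count).

    For each subject, the grid-cell accuracy is averaged over the inclusive
    TR window and over *all other* subjects; the argmax cell is assigned.
    Exact ties resolve to the smaller FWHM, then the smaller voxel count.

    Returns a list of dicts ``{"fwhm": ..., "n_voxels": ..., "fwhm_index":
    ..., "voxel_index": ...}``, one per subject.
    """
    lo, hi = int(tr_window[0]), int(tr_window[1])
    acc = grid.accuracy
    if not (0 <= lo <= hi < acc.shape[3]):
        raise ValueError("tr_window out of range")
    win = acc[:, :, :, lo:hi + 1].mean(axis=3)       # (S, F, V)
    n_sub = win.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    assignments = []
    for s in range(n_sub):
        others = np.delete(win, s, axis=0).mean(axis=0)
        if not np.all(np.isfinite(others)):
            raise ValueError("incomplete grid cells (non-finite accuracy)")
        # C-order argmax: first (smallest-FWHM, then smallest-count) winner
        f_idx, v_idx = np.unravel_index(np.argmax(others), others.shape)
        assignments.append({
            "fwhm": float(grid.fwhm_values[f_idx]),
            "n_voxels": int(grid.voxel_counts[v_idx]),
            "fwhm_index": int(f_idx),
            "voxel_index": int(v_idx),
        })
    return assignments
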