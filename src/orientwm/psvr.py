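"""Periodic support vector regression (pSVR) decoder for 180°-periodic
orientation labels.

An orientation θ ∈ [0°, 180°) is projected onto two sinusoids of the doubled
angle — x = sin(2θ·π/180), y = cos(2θ·π/180) — so that the circular label
becomes two real-valued targets. Each component is predicted independently
from the multivariate voxel pattern by an epsilon-insensitive support vector
regression with an RBF kernel, and the angle is recovered with the
four-quadrant inverse tangent θ̂ = atan2(x̂, ŷ). Training features are
min-max scaled to [0, 1] and the *training* scaling parameters are applied
to the test fold ("across-scaling"); cross-validation leaves one run out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

from . import metrics
from .preprocess import extract_trial_samples, feature_space_smooth

__all__ = ["DecoderSpec", "ReconstructionTimecourse", "encode_labels",
           "decode_labels", "scale_across", "fit_predict_pair", "loro_cv",
           "reconstruct_timecourse", "LABEL_COLUMNS"]

_DEG2RAD2 = np.pi / 90.0

#: label kinds the time-resolved decoder can reconstruct
LABEL_COLUMNS = {
    "target": "target_deg",
    "distractor": "distractor_deg",
    "probe_start": "probe_start_deg",
    "report": "response_deg",
}


@dataclass
class DecoderSpec:
    """pSVR hyperparameters.

    ``rbf_gamma`` follows the scikit-learn convention: the string
    ``"scale"`` means 1 / (n_features · Var(train features)), computed on
    the training fold only; a float fixes γ directly.
    """

    cost: float = 1.0
    epsilon_tube: float = 0.1
    rbf_gamma: float | str = "scale"

    def __post_init__(self):
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be nonnegative")


def encode_labels(theta):
    """Project orientations onto the two doubled-angle sinusoids.

    Returns an array of shape ``(..., 2)`` with x = sin(2θ·π/180) in column
    0 and the 45°-shifted sinusoid y = cos(2θ·π/180) in column 1.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta >= 180.0)):
        raise ValueError("orientations must lie in [0, 180)")
    a = theta * _DEG2RAD2
    return np.stack([np.sin(a), np.cos(a)], axis=-1)


def decode_labels(pair):
    """Recover orientations from (possibly unnormalized) sinusoid pairs.

    θ̂ = (atan2(x̂, ŷ) mod 2π) · 90/π, reduced into [0, 180). The zero
    vector has no defined angle and raises.
    """
    pair = np.asarray(pair, dtype=float)
    x, y = pair[..., 0], pair[..., 1]
    if np.any((x == 0) & (y == 0)):
        raise ValueError("cannot decode the zero vector")
    return np.mod(np.arctan2(x, y), 2.0 * np.pi) / _DEG2RAD2


def scale_across(train, test):
    """Per-feature min-max scaling fitted on train, applied to both.

    Train features map into [0, 1]; test values may exit that range.
    Constant training features map to 0 in both sets.

    Accepts and returns plain arrays (n_samples, n_features).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    constant = rng <= 0
    safe = np.where(constant, 1.0, rng)
    train_s = (train - lo) / safe
    test_s = (test - lo) / safe
    if constant.any():
        train_s[:, constant] = 0.0
        test_s[:, constant] = 0.0
    return train_s, test_s


def fit_predict_pair(train_X, train_pairs, test_X, spec=None):
    """Fit two independent RBF-kernel SVRs (one per sinusoid component) on
    the training fold and predict the test fold.

    ``train_pairs`` has shape (n_train, 2); returns (n_test, 2), unclipped.
    """
    spec = spec or DecoderSpec()
    train_X = np.asarray(train_X, dtype=float)
    train_pairs = np.asarray(train_pairs, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if len(train_X) < 2:
        raise ValueError("need at least 2 training rows")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature counts differ")
    preds = np.empty((len(test_X), 2))
    for k in range(2):
        y = train_pairs[:, k]
        if np.ptp(y) < 1e-12:
            warnings.warn("degenerate (constant) training labels; "
                          "predicting the constant", stacklevel=2)
            preds[:, k] = y[0]
            continue
        svr = SVR(kernel="rbf", C=spec.cost, epsilon=spec.epsilon_tube,
                  gamma=spec.rbf_gamma)
        preds[:, k] = svr.fit(train_X, y).predict(test_X)
    return preds


def loro_cv(samples, spec=None):
    """Leave-one-run-out cross-validated orientation predictions.

    For each run: across-scaling and both SVRs are fitted on all other
    runs, the held-out run is predicted, and the decoded angles are placed
    back in trial order. Every trial is predicted exactly once.
    """
    spec = spec or DecoderSpec()
    runs = np.unique(samples.run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    encoded = encode_labels(samples.labels)
    predicted = np.empty(samples.n_trials)
    for run in runs:
        test_mask = samples.run_ids == run
        train_X, test_X = scale_across(samples.X[~test_mask],
                                       samples.X[test_mask])
        pairs = fit_predict_pair(train_X, encoded[~test_mask], test_X, spec)
        predicted[test_mask] = decode_labels(pairs)
    return predicted


@dataclass
class ReconstructionTimecourse:
    """Per-TR, per-trial decoded orientations for one subject."""

    predictions: np.ndarray   # (n_trs, n_trials), degrees in [0, 180)
    true_deg: np.ndarray      # (n_trials,)
    run_ids: np.ndarray       # (n_trials,)
    label_kind: str = "target"
    tr_seconds: float = 0.8
    subject: str = "sim01"

    def bfca_per_tr(self):
        """BFCA timecourse, one value (percent) per decoded TR."""
        return np.array([metrics.bfca(self.true_deg, p)
                         for p in self.predictions])

    def mean_window(self, tr_window):
        """Average BFCA over an inclusive TR window."""
        return metrics.mean_window_accuracy(self, tr_window)

    def to_frame(self):
        """Long-format predictions table (subject, tr, trial, run,
        label_kind, true_deg, predicted_deg)."""
        import pandas as pd
        n_trs, n_trials = self.predictions.shape
        tr = np.repeat(np.arange(n_trs), n_trials)
        trial = np.tile(np.arange(1, n_trials + 1), n_trs)
        return pd.DataFrame({
            "subject": self.subject,
            "tr": tr,
            "trial": trial,
            "run": np.tile(self.run_ids, n_trs),
            "label_kind": self.label_kind,
            "true_deg": np.tile(self.true_deg, n_trs),
            "predicted_deg": self.predictions.ravel(),
        })

    def plot(self, ax=None, chance=50.0, **kwargs):
        """Plot the BFCA timecourse against time since delay onset."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        acc = self.bfca_per_tr()
        t = np.arange(len(acc)) * self.tr_seconds
        ax.plot(t, acc, **kwargs)
        ax.axhline(chance, color="gray", ls="--", lw=0.8)
        ax.set_xlabel("time since delay onset (s)")
        ax.set_ylabel("BFCA (%)")
        return ax


def reconstruct_timecourse(series, design, spec=None, smoothing=None,
                           label_kind="target", subject="sim01"):
    """Time-resolved reconstruction: extract → feature-smooth → LORO-decode
    at every TR offset of the trial window.

    ``series`` may be trialwise (a single decoded "TR") or TR-resolved,
    in which case the number of offsets is the per-trial TR count.
    """
    if label_kind not in LABEL_COLUMNS:
        raise ValueError(f"label_kind must be one of {sorted(LABEL_COLUMNS)}")
    label_col = LABEL_COLUMNS[label_kind]
    if label_col not in design.columns:
        raise KeyError(f"design has no column {label_col!r} needed for "
                       f"label_kind={label_kind!r}")
    if series.layout == "trialwise":
        offsets = [0]
    else:
        trs = series.meta.get("trs_per_trial")
        if trs is None:
            trs = int(np.diff(series.onsets[0]).min())
        offsets = list(range(int(trs)))
    preds = []
    true_deg = run_ids = None
    for off in offsets:
        samples = extract_trial_samples(series, design, tr_offset=off,
                                        label_col=label_col)
        if smoothing is not None:
            samples = feature_space_smooth(samples, smoothing)
        preds.append(loro_cv(samples, spec))
        if true_deg is None:
            true_deg, run_ids = samples.labels, samples.run_ids
    return ReconstructionTimecourse(np.vstack(preds), true_deg, run_ids,
                                    label_kind, series.tr_seconds, subject)
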