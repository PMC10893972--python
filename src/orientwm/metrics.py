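"""Feature-continuous accuracy (FCA) and its label-balance-corrected
integral (BFCA).

FCA rescales the absolute circular deviation between a true and a
reconstructed orientation (0–90° under 180° periodicity) linearly onto a
0–100% scale: 100% is perfect reconstruction, 50% (a 45° deviation) is
chance for circular orientation data, 0% is orthogonal. BFCA integrates the
trialwise FCA over the orientation space by the trapezoid rule across the
sorted true labels, which down-weights densely sampled label regions —
the continuous analogue of balanced accuracy for unbalanced classes.
"""

from __future__ import annotations

import numpy as np

from ._circ import circ_diff_180

__all__ = ["fca", "bfca", "mean_window_accuracy"]


def fca(true, predicted):
    """Trialwise feature-continuous accuracy in percent.

    ``FCA = (90 - |true - predicted|_circ) / 90 · 100`` with the absolute
    circular deviation taken under 180° periodicity. Vectorized.
    """
    dev = np.abs(circ_diff_180(true, predicted))
    return (90.0 - dev) / 90.0 * 100.0


def bfca(true, predicted):
    """Balanced FCA: trapezoid integral of trialwise FCA over [0°, 180°).

    Trials are sorted by true orientation; FCA values at duplicate true
    labels are averaged first (zero-width trapezoids would otherwise depend
    on order); the integral is closed circularly by re-appending the first
    point at its label + 180°, so a constant FCA integrates exactly to
    itself. Requires at least 2 trials.
    """
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.size < 2:
        raise ValueError("bfca needs at least 2 trials")
    f = fca(true, predicted)
    labels, inverse = np.unique(true, return_inverse=True)
    f_mean = np.bincount(inverse, weights=f) / np.bincount(inverse)
    x = np.append(labels, labels[0] + 180.0)
    y = np.append(f_mean, f_mean[0])
    return float(np.trapezoid(y, x) / 180.0)


def mean_window_accuracy(timecourse, tr_window):
    """Average per-TR BFCA over an inclusive TR window.

    ``timecourse`` is a :class:`~orientwm.psvr.ReconstructionTimecourse` (or
    any object with ``predictions`` of shape (n_trs, n_trials) and
    ``true_deg``); ``tr_window = (lo, hi)`` indexes TRs relative to the
    first decoded TR, both ends included.
    """
    lo, hi = int(tr_window[0]), int(tr_window[1])
    preds = np.asarray(timecourse.predictions, dtype=float)
    true = np.asarray(timecourse.true_deg, dtype=float)
    if not (0 <= lo <= hi < preds.shape[0]):
        raise ValueError("tr_window must be a nonempty inclusive range "
                         "within the decoded TRs")
    values = [bfca(true, preds[t]) for t in range(lo, hi + 1)]
    return float(np.mean(values))
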