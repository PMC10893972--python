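"""Circular arithmetic on 180°-periodic orientations.

A grating at θ and θ+180° is physically identical, so all orientation
arithmetic in this package lives on the half-circle [0, 180) and signed
differences live in [-90, 90).
"""

from __future__ import annotations

import numpy as np

PERIOD_DEG = 180.0


def wrap_orientation(theta):
    """Reduce an angle in degrees into the orientation space [0, 180)."""
    return np.mod(theta, PERIOD_DEG)


def circ_diff_180(a, b):
    """Signed minimal difference a - b under 180° periodicity.

    Parameters
    ----------
    a, b : array_like
        Orientations in degrees (any real values; reduced internally).

    Returns
    -------
    ndarray or scalar
        Signed difference in degrees, in [-90, 90).
    """
    return np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 90.0,
                  PERIOD_DEG) - 90.0
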