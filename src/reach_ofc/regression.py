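"""Shared least-squares slope used for both simulated and behavioral data.

The shift slope -- lateral position (relative to the target midline)
regressed on the imposed cursor shift -- is the study's central readout:
0 means vision is ignored, -1 means the shift is fully compensated. Model
readouts and the behavioral pipeline deliberately share this one code path.
"""

from __future__ import annotations

import numpy as np


class DegenerateDesignError(ValueError):
    """Raised when fewer than two distinct shift levels are available."""


def slope_on_shift(shifts: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope and intercept of ``values`` on ``shifts``.

    shifts : (k,) shift levels (m); values : (k,) or (k, T) responses (m).
    Returns (slope, intercept), each scalar or (T,).
    """
    shifts = np.asarray(shifts, dtype=float)
    values = np.asarray(values, dtype=float)
    if shifts.ndim != 1 or len(np.unique(shifts)) < 2:
        raise DegenerateDesignError("need at least two distinct shift levels")
    sc = shifts - shifts.mean()
    vc = values - values.mean(axis=0)
    slope = np.tensordot(sc, vc, axes=(0, 0)) / np.dot(sc, sc)
    intercept = values.mean(axis=0) - slope * shifts.mean()
    return slope, intercept
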