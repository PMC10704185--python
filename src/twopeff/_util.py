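"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["half_max_width", "check_uniform_grid"]


def half_max_width(x: np.ndarray, y: np.ndarray) -> float:
    """Full width of ``y`` at half its global maximum, by linear interpolation.

    The baseline is zero (profiles are expected to be background-free).
    Raises ``ValueError`` when the profile never drops below half maximum on
    either side of the peak within the sampled range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("profile must be two equal-length 1-D arrays (n >= 3)")
    ipk = int(np.argmax(y))
    ymax = y[ipk]
    if ymax <= 0:
        raise ValueError("profile maximum is not positive; width undefined")
    half = 0.5 * ymax
    below = y < half

    # right crossing: first sample past the peak strictly below half max
    right_part = below[ipk:]
    if not right_part.any():
        raise ValueError("profile never decays below half maximum on the right")
    j = ipk + int(np.argmax(right_part))  # y[j] < half, y[j-1] >= half
    frac = (y[j - 1] - half) / (y[j - 1] - y[j])
    x_right = x[j - 1] + frac * (x[j] - x[j - 1])

    # left crossing, scanning outward from the peak
    left_part = below[: ipk + 1][::-1]
    if not left_part.any():
        raise ValueError("profile never decays below half maximum on the left")
    k = ipk - int(np.argmax(left_part))  # y[k] < half, y[k+1] >= half
    frac = (half - y[k]) / (y[k + 1] - y[k])
    x_left = x[k] + frac * (x[k + 1] - x[k])

    return float(x_right - x_left)


def check_uniform_grid(t: np.ndarray, rtol: float = 1e-9) -> float:
    """Return the grid step of a strictly increasing uniform grid.

    Raises ``ValueError`` on non-monotone or non-uniform grids (relative
    deviation of any step from the mean step above ``rtol``).
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with at least 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > rtol * dt:
        raise ValueError("time grid is not uniform")
    return dt
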