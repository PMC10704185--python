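"""Intensity autocorrelation of pulse profiles and duration deconvolution.

Femtosecond pulses are too short for direct electronic measurement, so pulse
duration is inferred from the intensity autocorrelation function (ACF)

    A(τ) = ∫ P(t) P(t + τ) dt,

which an autocorrelator measures optically.  The ACF is symmetric and is
conventionally peak-normalized; its full width at half maximum (the
"autocorrelation time") is divided by a shape-dependent deconvolution factor
to report a pulse FWHM.  For a sech² pulse the factor conventionally quoted
by instrument vendors is 1.54 (the exact value is ≈ 1.5427), for a Gaussian
it is √2, and for a square pulse the ACF is triangular with the same width
as the pulse (factor 1).

Because many different pulse shapes share the same ACF width, the ACF alone
cannot reveal energy hidden in side lobes — which is exactly why measured
two-photon fluorescence can fall short of what the autocorrelation predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import half_max_width
from .pulses import PulseTrace

__all__ = [
    "DECONVOLUTION_FACTORS",
    "ACFTrace",
    "intensity_acf",
    "acf_width",
    "deconvolve_duration",
]

#: ACF width / pulse FWHM for the supported assumed shapes.  The sech² value
#: is the vendor convention 1.54, kept verbatim rather than the exact 1.5427.
DECONVOLUTION_FACTORS: dict[str, float] = {
    "sech2": 1.54,
    "gaussian": math.sqrt(2.0),
    "square": 1.0,
}


@dataclass(frozen=True)
class ACFTrace:
    """Normalized intensity autocorrelation on a symmetric lag grid."""

    lags: np.ndarray
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape:
            raise ValueError("lags and values must have the same shape")
        n = lags.size
        if n < 3 or n % 2 == 0:
            raise ValueError("ACF grid must have an odd number of samples centered on lag 0")
        if not np.allclose(lags, -lags[::-1], rtol=0, atol=1e-9 * abs(lags[-1])):
            raise ValueError("lag grid must be symmetric about 0")
        if not np.allclose(values, values[::-1], rtol=0, atol=1e-9):
            raise ValueError("ACF values must be symmetric within 1e-9")
        center = n // 2
        if abs(values[center] - 1.0) > 1e-12 or values.max() > 1.0 + 1e-12:
            raise ValueError("ACF must be peak-normalized to 1 at lag 0")
        if np.any(values < -1e-12):
            raise ValueError("ACF values must be non-negative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", np.clip(values, 0.0, None))


def intensity_acf(trace: PulseTrace) -> ACFTrace:
    """Compute the normalized intensity ACF of a pulse.

    The integral ∫P(t)P(t+τ)dt is evaluated as a trapezoidal sum on the
    trace's own grid, with the pulse treated as zero outside the grid, for
    every integer-sample lag in ±(span of the trace).  The result is
    symmetrized (to cancel floating-point asymmetry) and normalized to 1 at
    zero lag.
    """
    p = trace.powers
    t = trace.times
    n = p.size
    dt = trace.dt
    if float(np.trapezoid(p, t)) <= 0:
        raise ValueError("zero-energy trace: ACF normalization is undefined")

    # Rectangle-rule correlation, then trapezoid end-corrections: for a lag
    # of k samples the integrand f_i = p_i p_{i+k} gets half weight at i=0
    # and i=n-1 (all out-of-range products are zero).
    raw = np.correlate(p, p, mode="full") * dt  # index j ↔ lag k = j-(n-1)
    corr = np.zeros(2 * n - 1)
    corr[n - 1 :] += p[0] * p  # k ≥ 0: end term p_0·p_k
    corr[: n] += (p[-1] * p)[::-1]  # k ≤ 0: end term p_{n-1}·p_{n-1+k}
    acf = raw - 0.5 * dt * corr

    acf = 0.5 * (acf + acf[::-1])
    peak = acf[n - 1]
    if peak <= 0 or acf.max() > peak * (1 + 1e-12):
        raise ValueError("degenerate ACF: zero-lag value is not the maximum")
    values = acf / peak
    lags = (np.arange(2 * n - 1) - (n - 1)) * dt
    lags = 0.5 * (lags - lags[::-1])  # exact symmetry of the lag grid
    return ACFTrace(lags=lags, values=values, source_label=trace.label)


def acf_width(acf: ACFTrace) -> float:
    """Autocorrelation time: full width at half maximum of the ACF, seconds."""
    return half_max_width(acf.lags, acf.values)


def deconvolve_duration(width: float, assumed_shape: str = "sech2") -> float:
    """Convert an ACF width into a pulse FWHM under an assumed shape."""
    if not width > 0:
        raise ValueError("acf width must be positive")
    try:
        factor = DECONVOLUTION_FACTORS[assumed_shape]
    except KeyError:
        raise ValueError(
            f"unknown assumed shape {assumed_shape!r}; expected one of "
            f"{sorted(DECONVOLUTION_FACTORS)}"
        ) from None
    return width / factor
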