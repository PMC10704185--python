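"""Relative two-photon fluorescence predicted from pulse traces or scalars.

Two-photon excitation scales with the square of instantaneous power, so for
a train of identical pulses the steady-state fluorescence is

    F ∝ R ∫ P(t)² dt,

with R the repetition rate and P(t) a single pulse's power profile.  For an
assumed pulse shape this reduces to the scalar law F ∝ Pav² / (R·τp).  Both
forms only carry meaning as ratios between lasers; all values returned here
are relative (the proportionality constant is fixed to 1).

``predict_from_trace`` implements the measured-trace route: the trace (whose
amplitude units are arbitrary, as delivered by a FROG instrument) is first
rescaled so that it integrates to the pulse energy at the assumed average
power, then squared and integrated by trapezoidal sums and multiplied by R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulses import PulseTrace

__all__ = [
    "FluorescencePrediction",
    "predict_from_trace",
    "ideal_fluorescence",
    "frog_predicted_ratio",
]


@dataclass(frozen=True)
class FluorescencePrediction:
    """Relative fluorescence (W², arbitrary overall constant) plus context."""

    value: float
    rep_rate: float
    assumed_avg_power: float
    source_label: str = ""


def predict_from_trace(
    trace: PulseTrace, rep_rate: float, avg_power: float = 1.0
) -> FluorescencePrediction:
    """Predict relative 2p fluorescence from a single-pulse power trace.

    The trace is power-normalized to integrate to ``avg_power / rep_rate``
    (the per-pulse energy at the assumed average power), which makes the
    result invariant to the trace's arbitrary amplitude units, then
    F = rep_rate × ∫P²dt is returned.  F scales as ``avg_power²``.
    """
    if not rep_rate > 0:
        raise ValueError("rep_rate must be positive")
    if not avg_power > 0:
        raise ValueError("avg_power must be positive")
    integral = float(np.trapezoid(trace.powers, trace.times))
    if integral <= 0:
        raise ValueError("zero-integral trace: cannot power-normalize")
    scaled = trace.powers * ((avg_power / rep_rate) / integral)
    value = rep_rate * float(np.trapezoid(scaled**2, trace.times))
    return FluorescencePrediction(
        value=value,
        rep_rate=rep_rate,
        assumed_avg_power=avg_power,
        source_label=trace.label,
    )


def ideal_fluorescence(avg_power: float, rep_rate: float, pulse_duration: float) -> float:
    """Scalar-law relative fluorescence Pav²/(R·τp).

    This is the fluorescence an ideal laser (shape-for-shape identical to
    the reference) would produce; only ratios between calls are meaningful.
    """
    if not (avg_power > 0 and rep_rate > 0 and pulse_duration > 0):
        raise ValueError("avg_power, rep_rate and pulse_duration must all be positive")
    return avg_power**2 / (rep_rate * pulse_duration)


def frog_predicted_ratio(
    test_trace: PulseTrace,
    test_rate: float,
    ref_trace: PulseTrace,
    ref_rate: float,
    avg_power: float = 1.0,
) -> float:
    """Fluorescence of a test laser relative to a reference, from traces.

    Both lasers are assumed to run at the same average power (1 W by
    default); the ratio is independent of that choice.
    """
    test = predict_from_trace(test_trace, test_rate, avg_power)
    ref = predict_from_trace(ref_trace, ref_rate, avg_power)
    return test.value / ref.value
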