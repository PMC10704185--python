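"""Normalized fluorescence and two-photon excitation efficiency η.

A test laser's measured fluorescence F_test is compared with the
fluorescence F_ideal it *would* produce if it matched a reference laser's
pulse quality, after correcting for repetition rate R and pulse duration τp
via the scalar law F ∝ Pav²/(R·τp):

    η = F_test / F_ideal = (F_test / F_ref) · (R_test · τp,test) / (R_ref · τp,ref)

The reference laser is defined to have η = 1.  F_test/F_ref is obtained by
dividing every measured intensity by the value predicted at the same power
by a log–log regression of the reference laser's power series — which also
verifies the quadratic power dependence (slope 2) that certifies genuine
two-photon excitation without saturation or quenching.

Pairwise group comparisons use Welch two-sample t-tests with Holm step-down
adjustment across all pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Measurement",
    "LaserRecord",
    "RegressionFit",
    "EfficiencyResult",
    "StudyResult",
    "DEFAULT_POWER_RANGE",
    "reference_regression",
    "normalize_fluorescence",
    "eta_scale",
    "compute_eta",
    "pairwise_compare",
    "spotsize_efficiency_correlation",
    "run_study",
]

#: Default incident-power window (watts) over which the quadratic law is
#: trusted; beyond ~10 mW dye saturation and quenching bend the curve.
DEFAULT_POWER_RANGE: tuple[float, float] = (4e-3, 10e-3)


class Measurement(NamedTuple):
    """One fluorescence reading at a given average power."""

    power: float  # watts
    fluorescence: float  # normalized camera intensity, arbitrary units
    session_id: str = ""


@dataclass
class LaserRecord:
    """Scalar characterization of one laser plus its fluorescence readings.

    ``pulse_duration`` is the sech²-deconvolved FWHM as reported by an
    autocorrelator; only the ratio of durations between lasers enters η, so
    the assumed deconvolution shape cancels as long as it is consistent.
    """

    label: str
    rep_rate: float  # Hz
    pulse_duration: float  # seconds
    center_wavelength: float | None = None  # meters
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rep_rate > 0:
            raise ValueError(f"{self.label}: rep_rate must be positive")
        if not self.pulse_duration > 0:
            raise ValueError(f"{self.label}: pulse_duration must be positive")


class RegressionFit(NamedTuple):
    """Log–log power-law fit: log10(F) = intercept + slope·log10(P)."""

    slope: float
    intercept: float

    def predict(self, power: np.ndarray | float) -> np.ndarray | float:
        """Fluorescence predicted at ``power`` (watts)."""
        return 10.0 ** (self.intercept + self.slope * np.log10(power))


@dataclass(frozen=True)
class EfficiencyResult:
    """Per-laser normalized fluorescence and excitation efficiency."""

    label: str
    f_ratio_mean: float
    f_ratio_sd: float
    eta_mean: float
    eta_sd: float
    n_points: int


@dataclass(frozen=True)
class StudyResult:
    """Full multi-laser analysis: per-laser summaries plus diagnostics."""

    results: list[EfficiencyResult]
    pairwise: pd.DataFrame
    slopes: dict[str, float]
    points: pd.DataFrame  # per-point f_ratio and eta, one row per measurement


def _powers_fluor(record: LaserRecord) -> tuple[np.ndarray, np.ndarray]:
    if not record.measurements:
        raise ValueError(f"{record.label}: no measurements")
    p = np.array([m.power for m in record.measurements], dtype=float)
    f = np.array([m.fluorescence for m in record.measurements], dtype=float)
    return p, f


def reference_regression(ref: LaserRecord) -> RegressionFit:
    """Ordinary least-squares fit of log10(F) on log10(P) for the reference.

    Requires at least three measurements at distinct positive powers with
    positive fluorescence.  For clean two-photon excitation the slope is 2.
    """
    p, f = _powers_fluor(ref)
    if np.any(p <= 0) or np.any(f <= 0):
        raise ValueError("powers and fluorescence must be positive for a log-log fit")
    if np.unique(p).size < 3:
        raise ValueError("need at least 3 distinct power levels for the regression")
    fit = stats.linregress(np.log10(p), np.log10(f))
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept))


def normalize_fluorescence(
    test: LaserRecord,
    ref_fit: RegressionFit,
    ref_power_range: tuple[float, float] | None = DEFAULT_POWER_RANGE,
) -> np.ndarray:
    """Divide each measurement by the reference prediction at the same power.

    Returns one F_test/F_ref value per measurement.  Powers outside the
    reference fit's power range trigger an extrapolation warning (not an
    error); the values are still returned.
    """
    p, f = _powers_fluor(test)
    if ref_power_range is not None:
        lo, hi = ref_power_range
        outside = (p < lo) | (p > hi)
        if outside.any():
            warnings.warn(
                f"{test.label}: {int(outside.sum())} measurement(s) outside the "
                f"reference power range [{lo:g}, {hi:g}] W; extrapolating the "
                "reference regression",
                stacklevel=2,
            )
    return f / np.asarray(ref_fit.predict(p), dtype=float)


def eta_scale(test: LaserRecord, ref: LaserRecord) -> float:
    """(R_test·τp,test)/(R_ref·τp,ref): converts F_test/F_ref into η."""
    return (test.rep_rate * test.pulse_duration) / (ref.rep_rate * ref.pulse_duration)


def compute_eta(
    f_ratios: Sequence[float] | np.ndarray,
    test: LaserRecord,
    ref: LaserRecord,
) -> EfficiencyResult:
    """Scale normalized fluorescence ratios into per-point η and summarize.

    The sampling unit is one measurement (one power level in one session);
    the mean and sample standard deviation are taken over those points.
    """
    f = np.asarray(f_ratios, dtype=float)
    if f.size == 0:
        raise ValueError("f_ratios must be nonempty")
    etas = f * eta_scale(test, ref)
    sd = float(np.std(f, ddof=1)) if f.size > 1 else 0.0
    eta_sd = float(np.std(etas, ddof=1)) if etas.size > 1 else 0.0
    return EfficiencyResult(
        label=test.label,
        f_ratio_mean=float(np.mean(f)),
        f_ratio_sd=sd,
        eta_mean=float(np.mean(etas)),
        eta_sd=eta_sd,
        n_points=int(f.size),
    )


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def pairwise_compare(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups with Holm step-down adjustment.

    Returns an upper-triangular matrix of adjusted p-values (NaN on the
    diagonal and below), with rows/columns in the given group order.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {}
    for lab in labels:
        arr = np.asarray(groups[lab], dtype=float)
        if arr.size < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 points")
        arrays[lab] = arr
    pairs = list(itertools.combinations(labels, 2))
    raw = np.array([_welch_p(arrays[a], arrays[b]) for a, b in pairs])
    # Holm step-down: sort ascending, multiply by (m - rank), enforce monotonicity.
    m = raw.size
    order = np.argsort(raw)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * raw[idx]))
        adjusted[idx] = running
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (a, b), p in zip(pairs, adjusted):
        table.loc[a, b] = p
    return table


def spotsize_efficiency_correlation(
    etas: Sequence[float], widths: Sequence[float]
) -> float:
    """Pearson correlation between efficiency values and spot FWHM values."""
    x = np.asarray(etas, dtype=float)
    y = np.asarray(widths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("etas and widths must be equal-length with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def run_study(
    lasers: Iterable[LaserRecord],
    reference_label: str,
    slope_tolerance: float = 0.1,
    power_range: tuple[float, float] | None = DEFAULT_POWER_RANGE,
) -> StudyResult:
    """Full analysis of a multi-laser study against one reference laser.

    Fits the reference power-law, rejects any laser whose log–log slope
    deviates from 2 by more than ``slope_tolerance`` (the saturation /
    quenching guard), normalizes every measurement to the reference fit,
    scales into per-point η, and runs pairwise Welch/Holm comparisons when
    group sizes permit.
    """
    records = {rec.label: rec for rec in lasers}
    if reference_label not in records:
        raise ValueError(f"reference laser {reference_label!r} not among the records")
    ref = records[reference_label]
    ref_fit = reference_regression(ref)

    slopes: dict[str, float] = {}
    for label, rec in records.items():
        slope = reference_regression(rec).slope if label != reference_label else ref_fit.slope
        slopes[label] = slope
        if abs(slope - 2.0) > slope_tolerance:
            raise ValueError(
                f"{label}: log-log slope {slope:.3f} deviates from 2 by more than "
                f"{slope_tolerance:g}; saturation, quenching or non-2p signal suspected"
            )

    results: list[EfficiencyResult] = []
    eta_groups: dict[str, np.ndarray] = {}
    point_rows = []
    for label, rec in records.items():
        f_ratios = normalize_fluorescence(rec, ref_fit, power_range)
        res = compute_eta(f_ratios, rec, ref)
        results.append(res)
        etas = f_ratios * eta_scale(rec, ref)
        eta_groups[label] = etas
        for meas, fr, eta in zip(rec.measurements, f_ratios, etas):
            point_rows.append(
                {
                    "laser_label": label,
                    "session_id": meas.session_id,
                    "power_w": meas.power,
                    "fluorescence": meas.fluorescence,
                    "f_ratio": fr,
                    "eta": eta,
                }
            )

    if len(eta_groups) >= 2 and all(v.size >= 3 for v in eta_groups.values()):
        pairwise = pairwise_compare(eta_groups)
    else:
        labels = list(eta_groups)
        pairwise = pd.DataFrame(np.nan, index=labels, columns=labels)
    return StudyResult(
        results=results,
        pairwise=pairwise,
        slopes=slopes,
        points=pd.DataFrame(point_rows),
    )
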