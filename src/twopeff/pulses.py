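"""Parametric femtosecond pulse profiles on uniform time grids.

Two-photon (2p) fluorescence depends on the time-integral of the *squared*
instantaneous power of a pulse, so the pulse profile P(t) — not just its
average power and nominal duration — determines the fluorescence a laser can
excite.  This module generates canonical mode-locked pulse shapes (sech²,
Gaussian, square) and composite "low-quality" pulses built from a main peak
plus side lobes, and measures their basic scalar properties (energy, FWHM,
average power at a given repetition rate).

All internal quantities are SI: seconds, watts, joules.  Every integral in
the package is a trapezoidal sum on the trace's own uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import check_uniform_grid, half_max_width

__all__ = [
    "SECH2_FWHM_FACTOR",
    "GAUSSIAN_FWHM_FACTOR",
    "DECAY_THRESHOLD",
    "PulseTrace",
    "Lobe",
    "PulseShapeSpec",
    "generate_pulse",
    "pulse_energy",
    "fwhm",
    "average_power",
]

#: FWHM of ``sech²(t/t0)`` in units of t0: ``2·arccosh(√2)`` ≈ 1.7627.
SECH2_FWHM_FACTOR = float(2.0 * np.arccosh(np.sqrt(2.0)))

#: FWHM of a Gaussian in units of its standard deviation: ``2√(2 ln 2)`` ≈ 2.3548.
GAUSSIAN_FWHM_FACTOR = float(2.0 * np.sqrt(2.0 * np.log(2.0)))

#: A pulse is "fully contained" when both grid-end powers are below this
#: fraction of the peak power.
DECAY_THRESHOLD = 1e-6

_SHAPES = ("sech2", "gaussian", "square", "composite")


@dataclass(frozen=True)
class PulseTrace:
    """Sampled optical power versus time for a single, fully contained pulse.

    Parameters
    ----------
    times
        Strictly increasing uniform time grid, seconds.
    powers
        Instantaneous power, watts; all values must be non-negative.
    label
        Free-text identifier carried through downstream results.
    """

    times: np.ndarray
    powers: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        powers = np.asarray(self.powers, dtype=float)
        if times.shape != powers.shape:
            raise ValueError("times and powers must have the same shape")
        check_uniform_grid(times)
        if np.any(powers < 0):
            raise ValueError("pulse powers must be non-negative")
        pmax = powers.max() if powers.size else 0.0
        if pmax > 0 and (powers[0] > DECAY_THRESHOLD * pmax or powers[-1] > DECAY_THRESHOLD * pmax):
            raise ValueError(
                "pulse is not contained by the time grid: end powers exceed "
                f"{DECAY_THRESHOLD:g} of the peak; enlarge the grid span"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "powers", powers)

    @property
    def dt(self) -> float:
        """Grid step in seconds."""
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.times.size


@dataclass(frozen=True)
class Lobe:
    """One sech² lobe of a composite pulse.

    ``relative_height`` is the lobe peak power relative to the main lobe
    (exactly one lobe per composite must have height 1).
    """

    delay: float
    relative_height: float
    fwhm: float


@dataclass(frozen=True)
class PulseShapeSpec:
    """Parametric description of a pulse to be synthesized.

    Exactly one of ``energy`` (joules) or ``peak_power`` (watts) must be set.
    ``fwhm`` is the duration of the pulse (for composites: of the main lobe).
    """

    shape: str
    fwhm: float
    energy: float | None = None
    peak_power: float | None = None
    lobes: tuple[Lobe, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown pulse shape {self.shape!r}; expected one of {_SHAPES}")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if (self.energy is None) == (self.peak_power is None):
            raise ValueError("exactly one of energy or peak_power must be set")
        if self.energy is not None and not self.energy > 0:
            raise ValueError("energy must be positive")
        if self.peak_power is not None and not self.peak_power > 0:
            raise ValueError("peak_power must be positive")
        lobes = tuple(lb if isinstance(lb, Lobe) else Lobe(*lb) for lb in self.lobes)
        object.__setattr__(self, "lobes", lobes)
        if self.shape == "composite":
            if not lobes:
                raise ValueError("composite shape requires at least one lobe")
            heights = [lb.relative_height for lb in lobes]
            if any(not (0 < h <= 1) for h in heights):
                raise ValueError("lobe relative heights must lie in (0, 1]")
            if sum(h == 1.0 for h in heights) != 1:
                raise ValueError("composite requires exactly one lobe with relative height 1")
            if any(not lb.fwhm > 0 for lb in lobes):
                raise ValueError("lobe fwhm values must be positive")
        elif lobes:
            raise ValueError("lobes are only meaningful for the composite shape")

    def scaled(self, factor: float) -> "PulseShapeSpec":
        """Return a copy with every time parameter multiplied by ``factor``.

        This is a pure time rescale: energies are preserved, peak powers are
        not (a stretched pulse of equal energy has a lower peak).
        """
        return PulseShapeSpec(
            shape=self.shape,
            fwhm=self.fwhm * factor,
            energy=self.energy,
            peak_power=self.peak_power,
            lobes=tuple(
                Lobe(lb.delay * factor, lb.relative_height, lb.fwhm * factor) for lb in self.lobes
            ),
        )


def _sech2(t: np.ndarray, fwhm: float) -> np.ndarray:
    t0 = fwhm / SECH2_FWHM_FACTOR
    return 1.0 / np.cosh(t / t0) ** 2


def _render(spec: PulseShapeSpec, t: np.ndarray) -> np.ndarray:
    if spec.shape == "sech2":
        return _sech2(t, spec.fwhm)
    if spec.shape == "gaussian":
        sigma = spec.fwhm / GAUSSIAN_FWHM_FACTOR
        return np.exp(-0.5 * (t / sigma) ** 2)
    if spec.shape == "square":
        # Area-preserving rendering: each sample holds the coverage fraction
        # of its grid cell, so trapezoidal energy and interpolated FWHM are
        # accurate to a small fraction of one grid step.
        dt = t[1] - t[0]
        lo, hi = -0.5 * spec.fwhm, 0.5 * spec.fwhm
        cover = (np.minimum(t + 0.5 * dt, hi) - np.maximum(t - 0.5 * dt, lo)) / dt
        return np.clip(cover, 0.0, 1.0)
    # composite: pointwise sum of sech² lobes
    y = np.zeros_like(t)
    for lb in spec.lobes:
        y += lb.relative_height * _sech2(t - lb.delay, lb.fwhm)
    return y


def generate_pulse(
    spec: PulseShapeSpec,
    grid_span: float = 40.0,
    n_samples: int = 8192,
    label: str = "",
) -> PulseTrace:
    """Synthesize a pulse on a uniform grid centered on the main peak.

    Parameters
    ----------
    spec
        Shape, duration and amplitude of the pulse.
    grid_span
        Total grid length as a multiple of ``spec.fwhm`` (≥ 20).
    n_samples
        Number of grid samples (≥ 4096).

    The returned trace integrates (trapezoidally) to the requested energy
    exactly when ``spec.energy`` is set; with ``spec.peak_power`` set the
    maximum sample equals the requested peak instead.
    """
    if grid_span < 20:
        raise ValueError("grid_span must be at least 20 FWHM")
    if n_samples < 4096:
        raise ValueError("n_samples must be at least 4096")
    half = 0.5 * grid_span * spec.fwhm
    t = np.linspace(-half, half, int(n_samples))
    y = _render(spec, t)
    if spec.energy is not None:
        integral = float(np.trapezoid(y, t))
        if integral <= 0:
            raise ValueError("rendered pulse has zero energy")
        y = y * (spec.energy / integral)
    else:
        y = y * (spec.peak_power / y.max())
    pmax = y.max()
    if y[0] > DECAY_THRESHOLD * pmax or y[-1] > DECAY_THRESHOLD * pmax:
        raise ValueError(
            f"grid span {grid_span}×FWHM does not contain the pulse: end power "
            f"exceeds {DECAY_THRESHOLD:g} of the peak (check lobe delays)"
        )
    return PulseTrace(times=t, powers=y, label=label or spec.shape)


def pulse_energy(trace: PulseTrace) -> float:
    """Pulse energy in joules: trapezoidal integral of power over time."""
    return float(np.trapezoid(trace.powers, trace.times))


def fwhm(trace: PulseTrace) -> float:
    """Full width at half maximum of the pulse, seconds (linear interpolation)."""
    return half_max_width(trace.times, trace.powers)


def average_power(trace: PulseTrace, rep_rate: float) -> float:
    """Average optical power in watts for a pulse train at ``rep_rate`` Hz.

    Equals pulse energy × repetition rate.  Raises when the pulse duration is
    not short compared with the inter-pulse period (the pulse-train picture
    breaks down).
    """
    if not rep_rate > 0:
        raise ValueError("rep_rate must be positive")
    energy = pulse_energy(trace)
    if energy == 0:
        return 0.0
    if fwhm(trace) >= 1.0 / rep_rate:
        raise ValueError("pulse duration exceeds the inter-pulse period")
    return energy * rep_rate
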