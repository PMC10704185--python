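"""Synthetic data with known ground truth for every pipeline input.

Nothing in the analysis chain requires instrument data: this module
fabricates (a) single-pulse power traces, including composite "low quality"
pulses tuned to a prescribed autocorrelation width, (b) camera frames of the
excitation volume obeying the quadratic two-photon power law with a known
efficiency factor, and (c) complete multi-laser studies on disk in exactly
the formats the CLI consumes.

Generative model for the camera frames::

    counts = background + amplitude · η · (P / P_ref)² · G(x, z) · exposure + noise

with ``G`` an anisotropic Gaussian of prescribed lateral/axial FWHM centered
on a pixel, optional Poisson shot noise on the signal, additive Gaussian
read noise, and quantization to 12-bit depth scaled to 16 bits (multiples
of 16, ceiling 65520).  In a multi-laser study the amplitude of each laser
is additionally scaled by (R_ref·τ_ref)/(R·τ), so that the efficiency η of
the generated laser — relative to the study's reference — is exactly its
``true_eta``; η is a pure multiplicative factor on the quadratic signal.

All randomness flows from a single explicitly seeded generator per call;
identical specs and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

from .autocorr import acf_width, intensity_acf
from .images import SATURATION_CEILING, SpotImage
from .pulses import Lobe, PulseShapeSpec, PulseTrace, generate_pulse

__all__ = [
    "SyntheticLaserSpec",
    "SyntheticSceneSpec",
    "StudyPaths",
    "DEFAULT_POWERS",
    "quantize_12bit",
    "composite_spec",
    "make_pulse_trace",
    "make_spot_series",
    "simulate_study_frames",
    "make_study",
    "demo_lasers",
]

#: Six power levels spanning the 4–10 mW window of the quadratic regime (W).
DEFAULT_POWERS: tuple[float, ...] = tuple(np.linspace(4e-3, 10e-3, 6))

_EXPOSURE_MIN_MS = 600.0
_EXPOSURE_MAX_MS = 5000.0
#: Auto-exposure aims the peak at this raw count (comfortably below 65520).
_TARGET_PEAK_COUNTS = 48000.0


@dataclass(frozen=True)
class SyntheticLaserSpec:
    """Ground truth for one emulated laser."""

    label: str
    rep_rate: float  # Hz
    pulse_fwhm: float  # seconds (sech²-equivalent duration)
    true_eta: float = 1.0
    side_lobe_fraction: float = 0.0  # energy fraction outside the main peak
    noise_cv: float = 0.0  # multiplicative per-frame measurement noise
    wavelength: float = 920e-9  # meters
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.true_eta > 0:
            raise ValueError("true_eta must be positive")
        if not 0 <= self.side_lobe_fraction < 1:
            raise ValueError("side_lobe_fraction must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Camera/scene geometry shared by all frames of a study.

    ``spot_amplitude`` is the peak signal in counts/ms produced by the
    reference laser at ``reference_power``.  The default spot is elongated
    3:1 axially (side view of a focused beam), with pixel size chosen so the
    lateral FWHM is 0.5 μm.
    """

    image_shape: tuple[int, int] = (256, 256)
    spot_amplitude: float = 10.0  # counts per ms at reference_power
    fwhm_lateral_px: float = 8.0
    fwhm_axial_px: float = 24.0
    background_level: float = 100.0  # counts
    read_noise_sd: float = 2.0  # counts
    pixel_size: float = 6.25e-8  # meters per pixel
    reference_power: float = 10e-3  # watts

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if 2 * self.fwhm_axial_px > rows - 2 * 5 or 2 * self.fwhm_lateral_px > cols - 2 * 5:
            raise ValueError("spot does not fit inside the image with a 5-pixel margin")
        if self.spot_amplitude <= 0 or self.background_level < 0:
            raise ValueError("spot_amplitude must be positive, background non-negative")


class StudyPaths(NamedTuple):
    """Files written by :func:`make_study`."""

    manifest: Path
    lasers: Path
    ground_truth: Path
    image_dir: Path


def quantize_12bit(values: np.ndarray) -> np.ndarray:
    """Quantize float counts to 12-bit depth stored in 16 bits.

    Rounds to the nearest multiple of 16 and clips at the 65520 ceiling.
    """
    codes = np.clip(np.round(np.asarray(values, dtype=float) / 16.0), 0, 4095)
    return (codes.astype(np.uint16)) * np.uint16(16)


def composite_spec(
    fwhm: float,
    energy: float,
    side_lobe_fraction: float,
    lobe_delay: float | None = None,
    lobe_fwhm: float | None = None,
) -> PulseShapeSpec:
    """Main sech² peak plus two symmetric side lobes with a set energy share.

    ``side_lobe_fraction`` is the fraction of total pulse energy carried by
    the two side lobes together.  Lobe heights follow from the fact that a
    sech² lobe's energy is proportional to height × width.
    """
    if not 0 <= side_lobe_fraction < 1:
        raise ValueError("side_lobe_fraction must lie in [0, 1)")
    if side_lobe_fraction == 0:
        return PulseShapeSpec(shape="sech2", fwhm=fwhm, energy=energy)
    delay = lobe_delay if lobe_delay is not None else 4.0 * fwhm
    width = lobe_fwhm if lobe_fwhm is not None else fwhm
    f = side_lobe_fraction
    height = f * fwhm / (2.0 * width * (1.0 - f))
    if height > 1:
        raise ValueError(
            "side lobes would exceed the main peak; widen the lobes or lower the fraction"
        )
    lobes = (
        Lobe(-delay, height, width),
        Lobe(0.0, 1.0, fwhm),
        Lobe(delay, height, width),
    )
    return PulseShapeSpec(shape="composite", fwhm=fwhm, energy=energy, lobes=lobes)


def make_pulse_trace(
    spec: PulseShapeSpec,
    target_acf_width: float | None = None,
    grid_span: float = 40.0,
    n_samples: int = 8192,
    tol: float = 5e-3,
    max_iter: int = 40,
    label: str = "",
) -> PulseTrace:
    """Generate a pulse, optionally tuned to a target autocorrelation width.

    For composite shapes with ``target_acf_width`` set, every time parameter
    (lobe delays and widths) is rescaled by a common multiplier until the
    measured ACF width matches the target within ``tol`` (relative).  A pure
    time rescale leaves the side-lobe energy fractions untouched, and the
    ACF width responds linearly to it, so the iteration converges in a step
    or two (extra iterations absorb grid-discretization effects).
    """
    if target_acf_width is None:
        return generate_pulse(spec, grid_span=grid_span, n_samples=n_samples, label=label)
    if spec.shape != "composite":
        raise ValueError("target_acf_width tuning is only supported for composite shapes")
    current = spec
    for _ in range(max_iter):
        trace = generate_pulse(current, grid_span=grid_span, n_samples=n_samples, label=label)
        width = acf_width(intensity_acf(trace))
        rel = abs(width - target_acf_width) / target_acf_width
        if rel <= tol * 0.2:  # converge well inside the stated tolerance
            return trace
        current = current.scaled(target_acf_width / width)
    raise RuntimeError(
        f"ACF-width tuning did not converge to {target_acf_width:g} s within {max_iter} steps"
    )


def _gaussian_spot(shape: tuple[int, int], fwhm_lat: float, fwhm_ax: float) -> np.ndarray:
    rows, cols = shape
    r0, c0 = rows // 2, cols // 2  # spot centered exactly on a pixel
    r = np.arange(rows)[:, None] - r0
    c = np.arange(cols)[None, :] - c0
    ln2_4 = 4.0 * np.log(2.0)
    return np.exp(-ln2_4 * ((r / fwhm_ax) ** 2 + (c / fwhm_lat) ** 2))


def _auto_exposure(peak_counts_per_ms: float) -> float:
    if peak_counts_per_ms <= 0:
        return _EXPOSURE_MAX_MS
    return float(
        np.clip(_TARGET_PEAK_COUNTS / peak_counts_per_ms, _EXPOSURE_MIN_MS, _EXPOSURE_MAX_MS)
    )


def make_spot_series(
    laser: SyntheticLaserSpec,
    scene: SyntheticSceneSpec,
    powers: Sequence[float] = DEFAULT_POWERS,
    exposures: Sequence[float] | None = None,
    seed: int | None = None,
    shot_noise: bool = True,
    allow_saturation: bool = False,
    saturation_power: float | None = None,
    brightness_scale: float | None = None,
    session_id: str = "s1",
) -> list[SpotImage]:
    """Render one frame per power level for a single laser.

    ``exposures`` (ms) may be given per power; by default each frame uses an
    auto-exposure in the 600 ms–5 s range that puts the expected peak near
    (but below) the 12-bit ceiling, as in the acquisition protocol.
    ``saturation_power`` injects fluorophore saturation: the signal follows
    P²/(1 + (P/P_sat)²) instead of the pure quadratic law.
    ``brightness_scale`` overrides the default scale ``laser.true_eta`` (a
    study generator uses this to fold in repetition-rate and pulse-duration
    differences relative to its reference laser).
    """
    if exposures is not None and len(exposures) != len(powers):
        raise ValueError("powers and exposures must have the same length")
    rng = np.random.default_rng(seed if seed is not None else laser.seed)
    spot = _gaussian_spot(scene.image_shape, scene.fwhm_lateral_px, scene.fwhm_axial_px)
    scale = laser.true_eta if brightness_scale is None else brightness_scale
    frames: list[SpotImage] = []
    for i, power in enumerate(powers):
        quad = (power / scene.reference_power) ** 2
        if saturation_power is not None:
            quad /= 1.0 + (power / saturation_power) ** 2
        amp = scene.spot_amplitude * scale * quad  # peak counts per ms
        if laser.noise_cv > 0:
            amp *= max(0.05, 1.0 + laser.noise_cv * rng.standard_normal())
        exposure = float(exposures[i]) if exposures is not None else _auto_exposure(amp)
        expected_peak = scene.background_level + amp * exposure
        if expected_peak > SATURATION_CEILING and not allow_saturation:
            raise ValueError(
                f"{laser.label}: expected peak {expected_peak:.0f} counts exceeds the "
                f"{SATURATION_CEILING} ceiling; shorten the exposure or pass allow_saturation"
            )
        signal = amp * spot * exposure
        if shot_noise:
            signal = rng.poisson(signal).astype(float)
        img = scene.background_level + signal
        if scene.read_noise_sd > 0:
            img = img + rng.normal(0.0, scene.read_noise_sd, size=img.shape)
        frames.append(
            SpotImage(
                pixels=quantize_12bit(img),
                exposure_ms=exposure,
                incident_power=float(power),
                pixel_size=scene.pixel_size,
                laser_label=laser.label,
                session_id=session_id,
            )
        )
    return frames


def _relative_brightness(laser: SyntheticLaserSpec, ref: SyntheticLaserSpec) -> float:
    # Scalar law F ∝ η/(R·τp): brightness relative to the reference laser.
    return (
        laser.true_eta
        / ref.true_eta
        * (ref.rep_rate * ref.pulse_fwhm)
        / (laser.rep_rate * laser.pulse_fwhm)
    )


def simulate_study_frames(
    lasers: Sequence[SyntheticLaserSpec],
    reference_label: str,
    scene: SyntheticSceneSpec,
    powers: Sequence[float] = DEFAULT_POWERS,
    sessions: int = 1,
    seed: int | None = None,
    shot_noise: bool = True,
) -> list[SpotImage]:
    """Render all frames of a multi-laser study (in memory).

    Each laser's brightness is its ``true_eta`` scaled by the scalar law
    relative to the reference, so the analysis pipeline should recover
    ``true_eta`` for every laser (the reference recovering 1 by definition
    requires ``true_eta = 1`` on the reference spec).
    """
    labels = [l.label for l in lasers]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate laser labels in the study")
    by_label = {l.label: l for l in lasers}
    if reference_label not in by_label:
        raise ValueError(f"reference laser {reference_label!r} not among the specs")
    ref = by_label[reference_label]
    root = np.random.default_rng(seed)
    frames: list[SpotImage] = []
    for laser in lasers:
        for s in range(1, sessions + 1):
            sub_seed = int(root.integers(0, 2**31 - 1))
            frames.extend(
                make_spot_series(
                    laser,
                    scene,
                    powers=powers,
                    seed=sub_seed,
                    shot_noise=shot_noise,
                    brightness_scale=_relative_brightness(laser, ref),
                    session_id=f"s{s}",
                )
            )
    return frames


def make_study(
    lasers: Sequence[SyntheticLaserSpec],
    reference_label: str,
    scene: SyntheticSceneSpec,
    out_dir: str | Path,
    powers: Sequence[float] = DEFAULT_POWERS,
    sessions: int = 1,
    seed: int | None = None,
    shot_noise: bool = True,
) -> StudyPaths:
    """Write a complete synthetic study to disk.

    Produces ``images/*.tif`` (16-bit grayscale), ``manifest.csv`` (one row
    per frame: path, laser_label, session_id, power_mw, exposure_ms,
    pixel_size_um), ``lasers.csv`` (label, rep_rate_mhz, pulse_fs,
    wavelength_nm) and ``ground_truth.csv`` recording the generating η — a
    directory consumable verbatim by the ``spots`` and ``eta`` commands.
    """
    out = Path(out_dir)
    image_dir = out / "images"
    image_dir.mkdir(parents=True, exist_ok=True)
    frames = simulate_study_frames(
        lasers, reference_label, scene, powers=powers, sessions=sessions, seed=seed,
        shot_noise=shot_noise,
    )
    rows = []
    counters: dict[tuple[str, str], int] = {}
    for frame in frames:
        key = (frame.laser_label, frame.session_id)
        counters[key] = counters.get(key, 0) + 1
        safe = frame.laser_label.replace(" ", "-").replace("/", "-")
        name = f"{safe}_{frame.session_id}_{counters[key]:02d}.tif"
        tifffile.imwrite(image_dir / name, frame.pixels)
        rows.append(
            {
                "path": f"images/{name}",
                "laser_label": frame.laser_label,
                "session_id": frame.session_id,
                "power_mw": frame.incident_power * 1e3,
                "exposure_ms": frame.exposure_ms,
                "pixel_size_um": frame.pixel_size * 1e6,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    lasers_csv = out / "lasers.csv"
    pd.DataFrame(
        {
            "label": [l.label for l in lasers],
            "rep_rate_mhz": [l.rep_rate / 1e6 for l in lasers],
            "pulse_fs": [l.pulse_fwhm / 1e-15 for l in lasers],
            "wavelength_nm": [l.wavelength / 1e-9 for l in lasers],
        }
    ).to_csv(lasers_csv, index=False)

    truth_csv = out / "ground_truth.csv"
    pd.DataFrame(
        {
            "label": [l.label for l in lasers],
            "true_eta": [l.true_eta for l in lasers],
        }
    ).to_csv(truth_csv, index=False)
    return StudyPaths(manifest=manifest, lasers=lasers_csv, ground_truth=truth_csv,
                      image_dir=image_dir)


def demo_lasers(noise_cv: float = 0.01) -> list[SyntheticLaserSpec]:
    """A realistic six-laser benchmark: one Ti:Sa-class reference plus
    compact fiber/solid-state lasers with assorted efficiencies.

    Repetition rates and pulse durations are typical of commercial units in
    the 920–930 nm class; the efficiencies span the range seen in practice
    (a poor-pulse-quality fiber laser near 0.5 up to a unit slightly
    exceeding the reference).
    """
    return [
        SyntheticLaserSpec("tisa-ref", 80.78e6, 82e-15, true_eta=1.0, noise_cv=noise_cv),
        SyntheticLaserSpec("tisa-b", 80.36e6, 291e-15, true_eta=1.0, noise_cv=noise_cv),
        SyntheticLaserSpec("fiber-a", 80.51e6, 94e-15, true_eta=0.86, noise_cv=noise_cv),
        SyntheticLaserSpec(
            "fiber-b", 50.61e6, 111e-15, true_eta=0.52, side_lobe_fraction=0.3,
            noise_cv=noise_cv,
        ),
        SyntheticLaserSpec("solid-a", 80.13e6, 158e-15, true_eta=1.09, noise_cv=noise_cv),
        SyntheticLaserSpec("solid-b", 78.93e6, 88e-15, true_eta=0.90, noise_cv=noise_cv),
    ]
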