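"""Excitation-volume image analysis: intensity and spot-size extraction.

The excitation volume is imaged side-on, so a frame shows the x–z profile
of the fluorescent spot.  Frames are stored as 16-bit unsigned integers with
12-bit pixel depth scaled to 16 bits (counts are multiples of 16; the
saturation ceiling is 4095·16 = 65520).  Per the measurement protocol:

* each frame is converted to double precision, the mean of a background
  region (the outer border frame of the image) is subtracted, and the frame
  is divided by its exposure time in milliseconds;
* the brightest pixel of the normalized frame quantifies intensity;
* lateral and axial FWHM are read from the raw row and column profiles
  through the brightest pixel, with linear interpolation at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import half_max_width
from .efficiency import RegressionFit, LaserRecord, Measurement, reference_regression

__all__ = [
    "SATURATION_CEILING",
    "SpotImage",
    "SpotMeasurement",
    "normalize_image",
    "is_saturated",
    "peak_intensity",
    "profile_fwhm",
    "measure_spot",
    "power_series_analysis",
]

#: Highest representable count for 12-bit data scaled to 16 bits.
SATURATION_CEILING = 4095 * 16  # 65520

#: Fraction of each image dimension used as the background border frame.
DEFAULT_BACKGROUND_FRACTION = 0.1

_MIN_DIM = 64
_EDGE_MARGIN = 5


@dataclass
class SpotImage:
    """One camera frame of the excitation volume plus acquisition context."""

    pixels: np.ndarray  # 2-D uint16 counts
    exposure_ms: float
    incident_power: float  # watts
    pixel_size: float  # meters per pixel in the sample plane
    laser_label: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.dtype != np.uint16:
            raise ValueError(f"pixels must be uint16, got {px.dtype}")
        if min(px.shape) < _MIN_DIM:
            raise ValueError(f"image must be at least {_MIN_DIM}×{_MIN_DIM} pixels")
        if px.max(initial=0) > SATURATION_CEILING:
            raise ValueError(
                f"pixel value exceeds the 12-bit-in-16-bit ceiling {SATURATION_CEILING}"
            )
        if not self.exposure_ms > 0:
            raise ValueError("exposure must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = px


@dataclass(frozen=True)
class SpotMeasurement:
    """Quantities extracted from one normalized frame."""

    laser_label: str
    session_id: str
    incident_power: float
    peak_intensity: float  # counts per millisecond
    fwhm_lateral: float  # meters (row profile, x)
    fwhm_axial: float  # meters (column profile, z)
    peak_location: tuple[int, int]
    saturated: bool


def _background_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    if not 0 < fraction <= 0.25:
        raise ValueError("background fraction must lie in (0, 0.25]")
    rows, cols = shape
    br = max(1, round(fraction * rows))
    bc = max(1, round(fraction * cols))
    mask = np.zeros(shape, dtype=bool)
    mask[:br, :] = mask[-br:, :] = True
    mask[:, :bc] = mask[:, -bc:] = True
    return mask


def is_saturated(img: SpotImage) -> bool:
    """True when any pixel sits at the 12-bit ceiling."""
    return bool(img.pixels.max() >= SATURATION_CEILING)


def normalize_image(
    img: SpotImage, background_fraction: float = DEFAULT_BACKGROUND_FRACTION
) -> np.ndarray:
    """Background-subtract and exposure-normalize a frame.

    Returns a float image in counts per millisecond.  The background level
    is the mean over the outer border frame (``background_fraction`` of each
    dimension per side), which is spot-free in this imaging geometry.
    Negative values are retained (they are just noise around zero).
    """
    px = img.pixels.astype(float)
    bg = float(px[_background_mask(px.shape, background_fraction)].mean())
    return (px - bg) / img.exposure_ms


def peak_intensity(norm_img: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Value and (row, col) of the brightest normalized pixel.

    Ties are broken by first occurrence in row-major order.
    """
    flat = int(np.argmax(norm_img))
    loc = np.unravel_index(flat, norm_img.shape)
    return float(norm_img[loc]), (int(loc[0]), int(loc[1]))


def profile_fwhm(
    norm_img: np.ndarray,
    peak_location: tuple[int, int],
    pixel_size: float,
) -> tuple[float, float]:
    """Lateral and axial FWHM (meters) from the profiles through the peak.

    The lateral width is read along the row of the brightest pixel (x), the
    axial width along its column (z).  Raw one-pixel profiles are used with
    linear interpolation at half maximum — no smoothing and no fitting.
    The peak must sit at least 5 pixels from every image edge.
    """
    r, c = peak_location
    rows, cols = norm_img.shape
    if not (
        _EDGE_MARGIN <= r < rows - _EDGE_MARGIN and _EDGE_MARGIN <= c < cols - _EDGE_MARGIN
    ):
        raise ValueError("peak too close to the image edge for profile measurement")
    lateral_px = half_max_width(np.arange(cols, dtype=float), norm_img[r, :])
    axial_px = half_max_width(np.arange(rows, dtype=float), norm_img[:, c])
    return lateral_px * pixel_size, axial_px * pixel_size


def measure_spot(
    img: SpotImage, background_fraction: float = DEFAULT_BACKGROUND_FRACTION
) -> SpotMeasurement:
    """Run the full per-frame pipeline and package the results.

    Saturated frames are flagged (``saturated=True``) so that downstream
    intensity quantification can exclude them; geometry is still measured.
    """
    norm = normalize_image(img, background_fraction)
    value, loc = peak_intensity(norm)
    lateral, axial = profile_fwhm(norm, loc, img.pixel_size)
    return SpotMeasurement(
        laser_label=img.laser_label,
        session_id=img.session_id,
        incident_power=img.incident_power,
        peak_intensity=value,
        fwhm_lateral=lateral,
        fwhm_axial=axial,
        peak_location=loc,
        saturated=is_saturated(img),
    )


def power_series_analysis(
    powers: np.ndarray,
    intensities: np.ndarray,
    slope_tolerance: float = 0.1,
) -> tuple[float, dict[float, float], bool]:
    """Log–log slope of peak intensity versus incident power.

    Returns ``(slope, per-power mean intensity, flagged)`` where ``flagged``
    is True when the slope deviates from the two-photon value 2 by more than
    ``slope_tolerance`` — the signature of saturation (slope < 2) or of a
    non-quadratic signal.
    """
    powers = np.asarray(powers, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    record = LaserRecord(
        label="series",
        rep_rate=1.0,
        pulse_duration=1.0,
        measurements=[Measurement(p, f) for p, f in zip(powers, intensities)],
    )
    fit: RegressionFit = reference_regression(record)
    means: dict[float, float] = {}
    for p in np.unique(powers):
        means[float(p)] = float(intensities[powers == p].mean())
    flagged = abs(fit.slope - 2.0) > slope_tolerance
    return fit.slope, means, flagged
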